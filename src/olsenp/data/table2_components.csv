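method,soil_class,slope,intercept,r_squared,n_samples,jurisdiction,source_ref
mehlich3,non_calcareous,0.33,6.9,0.88,91,US,wolf_baker_1985
mehlich3,non_calcareous,0.47,1.2,0.79,180,US,mallarino_2003
mehlich3,calcareous,0.45,1.8,0.81,60,US,mallarino_2003
mehlich3,non_calcareous,0.70,-0.6,0.71,66,Italy,iatrou_2014
mehlich3,calcareous,0.37,0.4,0.73,54,Italy,iatrou_2014
bray1,non_calcareous,0.43,2.4,0.68,180,US,mallarino_2003
bray1,non_calcareous,0.68,3.9,0.95,165,US,sharpley_1985
bray1,non_calcareous,0.30,2.9,0.85,91,US,wolf_baker_1985
abdpta,any,1.81,4.1,0.50,35,India,singh_2005
resin,non_calcareous,0.71,0.1,0.91,59,US,schoenau_1991
resin,calcareous,0.94,0.0,,30,US,kuo_1996
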