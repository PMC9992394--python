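"""Log-scale additive modelling of Olsen P with retransformation correction.

The harmonized concentrations are strongly right-skewed, so the model is fit
to ln(Olsen P), which is approximately normal (checked with a Shapiro-Wilk
statistic at fit time).  Correlated monthly covariate families are first
reduced by PCA to the smallest set of components reaching a cumulative
explained-variance target.  The predictive model is a Gaussian generalized
additive model: penalized B-spline smooths for continuous covariates and
principal-component scores plus factor terms (country, biome, development
status, soil group), fit with statsmodels' GAM machinery.

Because countries absent from the training data cannot otherwise be
predicted, a seeded 5% sample of each country's rows is relabelled "other"
before fitting, so the model carries a weighted-average country level that
unseen countries map onto at prediction time.

Back-transforming exp(yhat) from a log-scale model underestimates the
conditional mean; predictions are multiplied by Duan's smearing factor
S = mean(exp(residuals)), assumed constant over the prediction range
(homoscedastic residuals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "extract_predictors", "pca_reduce", "PCAReduction",
    "other_country_augment", "smearing_factor", "model_metrics",
    "OlsenPModel", "OlsenPResults",
]


# ---------------------------------------------------------------------------
# predictor assembly

def extract_predictors(samples: pd.DataFrame, rasters: dict) -> pd.DataFrame:
    """Nearest-cell extraction of raster covariates at sample coordinates.

    ``rasters`` maps variable name -> Raster.  Categorical rasters (with a
    label map) yield their string labels.  Rows with any missing covariate
    are flagged ``no_coverage=True`` and should be excluded from fitting.
    """
    out = samples.copy()
    missing = np.zeros(len(out), dtype=bool)
    lons = out["longitude"].to_numpy(float)
    lats = out["latitude"].to_numpy(float)
    for name, raster in rasters.items():
        vals = np.array([raster.sample(x, y) for x, y in zip(lons, lats)])
        if raster.labels:
            lab = np.array([
                raster.labels.get(int(v), None) if np.isfinite(v) else None
                for v in vals], dtype=object)
            missing |= pd.isna(lab)
            out[name] = lab
        else:
            missing |= ~np.isfinite(vals)
            out[name] = vals
    out["no_coverage"] = missing
    n_bad = int(missing.sum())
    if n_bad:
        logger.info("extract_predictors: %d/%d rows lack coverage for at least "
                    "one covariate", n_bad, len(out))
    return out


@dataclass
class PCAReduction:
    """Fitted standardize-then-rotate reduction of a correlated variable block."""

    variables: list
    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray          # (k, p) loadings
    explained_ratio: np.ndarray     # all p shares, sum to 1
    n_retained: int

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_ratio[: self.n_retained].sum())

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        X = (df[self.variables].to_numpy(float) - self.mean) / self.std
        return X @ self.components[: self.n_retained].T


def pca_reduce(
    X, variance_target: float = 0.95, variables: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, PCAReduction]:
    """Reduce a column-standardized covariate block by principal components.

    Returns the scores of the smallest leading set of components whose
    cumulative explained variance reaches ``variance_target``, plus the
    fitted reduction (loadings and variance shares).
    """
    from sklearn.decomposition import PCA

    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 columns")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [i for i, s in enumerate(std) if s == 0]
        raise ValueError(f"zero variance predictor at column(s) {bad}")
    Z = (X - mean) / std
    pca = PCA()
    scores = pca.fit_transform(Z)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    if variance_target >= 1.0:
        k = len(ratio)
    else:
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, len(ratio))
    red = PCAReduction(
        variables=list(variables) if variables is not None
        else [f"x{i}" for i in range(X.shape[1])],
        mean=mean, std=std, components=pca.components_,
        explained_ratio=ratio, n_retained=k)
    return scores[:, :k], red


def other_country_augment(
    df: pd.DataFrame,
    fraction: float = 0.05,
    seed: int = 0,
    country_col: str = "country",
    mode: str = "rename",
) -> pd.DataFrame:
    """Relabel a seeded per-country sample of rows as country "other".

    For each country, ``round(fraction * n)`` rows (half away from zero) are
    selected; ``mode='rename'`` relabels them in place, ``mode='append'``
    appends relabelled copies instead.  Numeric covariates are untouched.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    if mode not in ("rename", "append"):
        raise ValueError(f"unknown mode {mode!r}")
    if df.empty:
        return df.copy()
    rng = np.random.default_rng(seed)
    out = df.copy().reset_index(drop=True)
    picked = []
    for _, idx in out.groupby(country_col, sort=True).indices.items():
        k = int(np.floor(fraction * len(idx) + 0.5))
        if k > 0:
            picked.extend(rng.choice(idx, size=k, replace=False).tolist())
    if mode == "rename":
        out.loc[picked, country_col] = "other"
        return out
    extra = out.loc[picked].copy()
    extra[country_col] = "other"
    return pd.concat([out, extra], ignore_index=True)


def m_names(smooth_terms, k):
    """Variable names for the smoother: named terms then PC scores."""
    return list(smooth_terms) + [f"PC{i + 1}" for i in range(k - len(smooth_terms))]


# ---------------------------------------------------------------------------
# smearing and metrics

def smearing_factor(residuals) -> float:
    """Duan's smearing estimate S = (1/n) sum exp(residual_i).

    For mean-zero residuals S >= 1 by Jensen's inequality; multiplying
    exp(yhat) by S removes the downward bias of naive back-transformation.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residuals")
    return float(np.mean(np.exp(r)))


def model_metrics(observed, predicted, aic: Optional[float] = None) -> dict:
    """R^2 (squared correlation, %), Nash-Sutcliffe efficiency, and AIC.

    NSE = 1 - sum((o-p)^2) / sum((o-mean(o))^2): 1 is a perfect match and 0
    is no better than predicting the observed mean.  AIC is passed through
    from the fitted model object (it is not a function of the two vectors).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size or o.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    sso = np.sum((o - o.mean()) ** 2)
    if sso == 0:
        raise ValueError("zero variance in observed values")
    if np.ptp(p) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2) * 100.0
    nse = float(1.0 - np.sum((o - p) ** 2) / sso)
    return {"r_squared": r2, "nse": nse, "aic": aic}


# ---------------------------------------------------------------------------
# the model object

class OlsenPModel:
    """Additive model of ln(Olsen P) over smooth and factor covariates.

    Parameters
    ----------
    data : DataFrame
        One row per harmonized sample; must contain ``response_col``, the
        smooth-term columns, factor columns and any PCA-block columns.
    smooth_terms : sequence of str
        Continuous covariates entering as penalized B-spline smooths.
    factor_terms : sequence of str
        Categorical covariates entering as dummy-coded linear terms.
    pca_vars : sequence of str, optional
        Correlated continuous block reduced to principal components before
        fitting; the retained scores enter as additional smooth terms.
    variance_target : float
        Cumulative explained-variance target for the retained components.
    spline_df, spline_degree, alpha
        B-spline basis size, degree and penalty weight per smooth term.
    augment_fraction : float
        Per-country share of rows relabelled "other" before fitting
        (0 disables augmentation).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response_col: str = "olsen_p_0_20",
        smooth_terms: Sequence[str] = (),
        factor_terms: Sequence[str] = ("country",),
        pca_vars: Optional[Sequence[str]] = None,
        variance_target: float = 0.95,
        spline_df: int = 6,
        spline_degree: int = 3,
        alpha: float = 0.0,
        augment_fraction: float = 0.05,
        augment_mode: str = "rename",
        country_col: str = "country",
    ):
        self.response_col = response_col
        self.smooth_terms = list(smooth_terms)
        self.factor_terms = list(factor_terms)
        self.pca_vars = list(pca_vars) if pca_vars else []
        self.variance_target = variance_target
        self.spline_df = spline_df
        self.spline_degree = spline_degree
        self.alpha = alpha
        self.augment_fraction = augment_fraction
        self.augment_mode = augment_mode
        self.country_col = country_col

        needed = ({response_col} | set(self.smooth_terms)
                  | set(self.factor_terms) | set(self.pca_vars))
        missing_cols = needed - set(data.columns)
        if missing_cols:
            raise ValueError(f"data lacks columns {sorted(missing_cols)}")
        work = data.loc[:, sorted(needed)].copy()
        complete = work.notna().all(axis=1)
        if "no_coverage" in data.columns:
            complete &= ~data["no_coverage"].astype(bool)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("dropping %d rows with missing covariates", dropped)
        work = work.loc[complete]
        positive = work[response_col] > 0
        if (~positive).any():
            logger.info("dropping %d non-positive responses", int((~positive).sum()))
        self.data = work.loc[positive].reset_index(drop=True)
        if len(self.data) < 10:
            raise ValueError("too few complete rows to fit")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "OlsenPModel":
        return cls(data, **kwargs)

    # -- internal design construction --------------------------------------

    def _design(self, df, pca_red, smoother=None, factor_levels=None):
        """(exog, exog_smooth, smoother, factor_levels) for a data subset."""
        from statsmodels.gam.api import BSplines

        cols = [np.log(df[self.response_col].to_numpy(float))]
        smooth_mat = [df[c].to_numpy(float) for c in self.smooth_terms]
        if pca_red is not None:
            scores = pca_red.transform(df)
            smooth_mat.extend(scores.T)
        Xs = np.column_stack(smooth_mat) if smooth_mat else None

        if factor_levels is None:
            factor_levels = {}
            for f in self.factor_terms:
                levels = sorted(map(str, df[f].unique()))
                if f == self.country_col and "other" not in levels \
                        and self.augment_fraction > 0:
                    levels.append("other")
                factor_levels[f] = levels
        dummies = [np.ones(len(df))]
        names = ["const"]
        for f in self.factor_terms:
            levels = factor_levels[f]
            vals = df[f].astype(str)
            if f == self.country_col:
                vals = vals.where(vals.isin(levels), "other")
            elif (~vals.isin(levels)).any():
                unseen = sorted(set(vals) - set(levels))
                raise ValueError(f"unseen level(s) {unseen} for factor {f!r}")
            for lev in levels[1:]:  # first level is the reference
                dummies.append((vals == lev).to_numpy(float))
                names.append(f"{f}[{lev}]")
        exog = np.column_stack(dummies)

        if Xs is not None:
            if smoother is None:
                k = Xs.shape[1]
                smoother = BSplines(
                    Xs, df=[self.spline_df] * k,
                    degree=[self.spline_degree] * k,
                    include_intercept=False,
                    variable_names=m_names(self.smooth_terms, k))
        return cols[0], exog, names, Xs, smoother, factor_levels, None

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        split: Optional[float] = 0.7,
        seed: int = 0,
    ) -> "OlsenPResults":
        """Fit the additive model, optionally on a seeded train fraction.

        ``split=0.7`` trains on a random 70% and evaluates metrics on the
        held-out 30%; ``split=None`` fits and evaluates on all data (the
        configuration used for a final production model).
        """
        from statsmodels.gam.api import GLMGam

        df = self.data
        if self.augment_fraction > 0 and self.country_col in self.factor_terms:
            df = other_country_augment(
                df, self.augment_fraction, seed=seed,
                country_col=self.country_col, mode=self.augment_mode)

        y_all = np.log(df[self.response_col].to_numpy(float))
        n_shapiro = min(len(y_all), 5000)
        sw_stat, sw_p = stats.shapiro(y_all[:n_shapiro])
        if sw_p < 0.05:
            warnings.warn(
                f"log-response departs from normality (Shapiro-Wilk W="
                f"{sw_stat:.3f}, p={sw_p:.2g}); fitting proceeds", stacklevel=2)

        rng = np.random.default_rng(seed)
        n = len(df)
        if split is not None:
            if not (0 < split <= 1):
                raise ValueError("split must lie in (0, 1]")
            perm = rng.permutation(n)
            n_train = int(round(split * n))
            train_idx, test_idx = perm[:n_train], perm[n_train:]
        else:
            train_idx, test_idx = np.arange(n), np.array([], dtype=int)
        train = df.iloc[train_idx]
        test = df.iloc[test_idx]

        pca_red = None
        if self.pca_vars:
            _, pca_red = pca_reduce(
                train[self.pca_vars], self.variance_target)

        (y_tr, exog_tr, names, Xs_tr, smoother, levels, _) = self._design(
            train, pca_red)

        if smoother is not None:
            k = len(smoother.smoothers)
            gam = GLMGam(y_tr, exog=exog_tr, smoother=smoother,
                         alpha=[self.alpha] * k)
            res = gam.fit()
        else:
            import statsmodels.api as sm
            res = sm.OLS(y_tr, exog_tr).fit()

        fitted_tr = np.asarray(res.fittedvalues)
        residuals = y_tr - fitted_tr
        S = smearing_factor(residuals)

        results = OlsenPResults(
            model=self, _res=res, smoother=smoother, pca=pca_red,
            factor_levels=levels, exog_names=names,
            residuals=residuals, smearing=S,
            train_index=train_idx, test_index=test_idx,
            split=split, seed=seed,
            shapiro=(float(sw_stat), float(sw_p)),
            train_data=train.reset_index(drop=True),
        )

        eval_df = test if len(test) else train
        y_eval = np.log(eval_df[self.response_col].to_numpy(float))
        yhat_eval = results.predict_log(eval_df)
        results.metrics = model_metrics(y_eval, yhat_eval, aic=float(res.aic))
        results.metrics["evaluated_on"] = "test" if len(test) else "train"
        return results


@dataclass
class OlsenPResults:
    """Fitted log-scale additive model with smearing correction.

    ``predict`` returns smearing-corrected concentrations in mg/kg;
    ``predict_log`` returns the raw log-scale linear predictor.
    """

    model: OlsenPModel
    _res: object
    smoother: object
    pca: Optional[PCAReduction]
    factor_levels: dict
    exog_names: list
    residuals: np.ndarray
    smearing: float
    train_index: np.ndarray
    test_index: np.ndarray
    split: Optional[float]
    seed: int
    shapiro: tuple
    train_data: pd.DataFrame
    metrics: dict = field(default_factory=dict)

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals, ddof=1))

    @property
    def aic(self) -> float:
        return float(self._res.aic)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._res.params)

    def predict_log(self, newdata: pd.DataFrame) -> np.ndarray:
        """Log-scale prediction; unseen countries route to the "other" level."""
        m = self.model
        df = newdata.copy()
        if m.response_col not in df.columns:
            df[m.response_col] = 1.0  # design builder needs the column
        unseen = None
        if m.country_col in m.factor_terms:
            lev = set(self.factor_levels[m.country_col])
            mask = ~df[m.country_col].astype(str).isin(lev)
            if mask.any():
                unseen = sorted(df.loc[mask, m.country_col].astype(str).unique())
                logger.info("routing unseen countries %s to 'other'", unseen)
        _, exog, _, Xs, _, _, _ = m._design(
            df, self.pca, smoother=self.smoother,
            factor_levels=self.factor_levels)
        if self.smoother is not None:
            # clip into the training span: B-spline bases vanish outside it
            lo = self.smoother.x.min(axis=0)
            hi = self.smoother.x.max(axis=0)
            return np.asarray(self._res.predict(
                exog=exog, exog_smooth=np.clip(Xs, lo, hi)))
        return np.asarray(self._res.predict(exog))

    def predict(self, newdata: pd.DataFrame, correct_bias: bool = True) -> np.ndarray:
        """Concentration prediction in mg/kg: S * exp(yhat_log)."""
        yhat = np.exp(self.predict_log(newdata))
        return self.smearing * yhat if correct_bias else yhat

    def predict_grid(self, rasters: dict, extra: Optional[dict] = None):
        """Predict a concentration raster from covariate rasters.

        ``rasters`` maps every model covariate to an aligned Raster (factor
        covariates use labelled categorical rasters); ``extra`` supplies
        constant values for covariates without a raster.  Cells where any
        covariate is missing are nodata.
        """
        first = next(iter(rasters.values()))
        lon, lat = first.cell_centers()
        table = pd.DataFrame({"longitude": lon.ravel(), "latitude": lat.ravel()})
        table = extract_predictors(table, rasters)
        if extra:
            for kcol, v in extra.items():
                table[kcol] = v
        ok = ~table["no_coverage"].to_numpy(bool)
        out = np.full(lon.size, np.nan)
        if ok.any():
            out[ok] = self.predict(table.loc[ok])
        return first.copy_with(out.reshape(lon.shape))

    def summary(self) -> str:
        m = self.model
        k_pc = 0 if self.pca is None else self.pca.n_retained
        lines = [
            "Olsen P additive model (response: ln mg/kg)",
            "=" * 52,
            f"n train / test:        {len(self.train_index)} / {len(self.test_index)}",
            f"smooth terms:          {', '.join(m.smooth_terms) or '(none)'}",
            f"factor terms:          {', '.join(m.factor_terms) or '(none)'}",
        ]
        if self.pca is not None:
            lines.append(
                f"PCA block:             {len(self.pca.variables)} vars -> "
                f"{k_pc} components "
                f"({100 * self.pca.cumulative_explained:.1f}% variance)")
        lines += [
            f"Shapiro-Wilk (log y):  W={self.shapiro[0]:.3f}, p={self.shapiro[1]:.3g}",
            f"residual SD (log):     {self.residual_sd:.4f}",
            f"smearing factor S:     {self.smearing:.4f}",
            f"R-squared (%):         {self.metrics.get('r_squared', float('nan')):.1f}",
            f"NSE:                   {self.metrics.get('nse', float('nan')):.3f}",
            f"AIC:                   {self.aic:.1f}",
            f"metrics evaluated on:  {self.metrics.get('evaluated_on', '?')}",
        ]
        return "\n".join(lines)
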