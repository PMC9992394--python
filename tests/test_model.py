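"""PCA reduction, country augmentation, additive fit, smearing and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from olsenp.model import (
    OlsenPModel, model_metrics, other_country_augment, pca_reduce,
    smearing_factor,
)


class TestPCAReduce:
    def test_perfectly_correlated_columns_need_one_component(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, 2 * x + 1])
        scores, red = pca_reduce(X, variance_target=0.95)
        assert red.n_retained == 1
        assert red.explained_ratio[0] == pytest.approx(1.0)

    def test_independent_columns_share_variance_equally(self, rng):
        X = rng.normal(size=(1000, 5))
        _, red = pca_reduce(X, variance_target=1.0)
        np.testing.assert_allclose(red.explained_ratio, 0.2, atol=0.05)
        assert red.explained_ratio.sum() == pytest.approx(1.0)

    def test_variance_target_one_returns_all(self, rng):
        X = rng.normal(size=(50, 4))
        scores, red = pca_reduce(X, variance_target=1.0)
        assert red.n_retained == 4 and scores.shape == (50, 4)

    def test_retained_set_is_minimal_prefix(self, rng):
        X = rng.normal(size=(300, 6))
        X[:, 0] *= 10  # dominant direction
        _, red = pca_reduce(X, variance_target=0.5)
        cum = np.cumsum(red.explained_ratio)
        k = red.n_retained
        assert cum[k - 1] >= 0.5
        assert k == 1 or cum[k - 2] < 0.5

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.raises(ValueError, match="[Zz]ero variance"):
            pca_reduce(X)


class TestOtherCountryAugment:
    def _table(self, n_per_country, countries=("a", "b")):
        rows = []
        for c in countries:
            for i in range(n_per_country):
                rows.append({"country": c, "x": float(i)})
        return pd.DataFrame(rows)

    def test_five_percent_relabelled(self):
        df = self._table(100)
        out = other_country_augment(df, fraction=0.05, seed=1)
        assert len(out) == len(df)
        assert (out["country"] == "other").sum() == 10  # 5 per 100-row country
        assert out["x"].equals(df["x"])  # numeric covariates untouched

    def test_append_mode_adds_copies(self):
        df = self._table(100)
        out = other_country_augment(df, fraction=0.05, seed=1, mode="append")
        assert len(out) == len(df) + 10
        assert set(out["country"]) == {"a", "b", "other"}

    def test_seed_determinism(self):
        df = self._table(40)
        a = other_country_augment(df, 0.05, seed=9)
        b = other_country_augment(df, 0.05, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_and_bad_fraction(self):
        assert other_country_augment(pd.DataFrame({"country": []}), 0.05).empty
        with pytest.raises(ValueError):
            other_country_augment(self._table(10), 1.5)

    def test_rounding_half_away_from_zero(self):
        out = other_country_augment(self._table(30), fraction=0.05, seed=0)
        # 30 * 0.05 = 1.5 -> 2 per country
        assert (out["country"] == "other").sum() == 4


class TestSmearing:
    def test_zero_residuals(self):
        assert smearing_factor([0.0, 0.0, 0.0]) == 1.0

    def test_symmetric_log_two(self):
        assert smearing_factor([np.log(2), -np.log(2)]) == pytest.approx(1.25)

    def test_small_residuals(self):
        got = smearing_factor([0.1, -0.1])
        assert got == pytest.approx((np.e ** 0.1 + np.e ** -0.1) / 2)
        assert got == pytest.approx(1.0050, abs=5e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smearing_factor([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=40))
    def test_jensen_lower_bound(self, residuals):
        r = np.array(residuals) - np.mean(residuals)  # mean-zero
        assert smearing_factor(r) >= 1.0 - 1e-12
        assert smearing_factor(residuals) >= np.exp(np.mean(residuals)) - 1e-12


class TestModelMetrics:
    def test_perfect_prediction(self):
        m = model_metrics([1, 2, 3, 4], [1, 2, 3, 4])
        assert m["r_squared"] == pytest.approx(100.0)
        assert m["nse"] == pytest.approx(1.0)

    def test_mean_baseline_has_zero_nse(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        m = model_metrics(o, np.full(4, o.mean()))
        assert m["nse"] == pytest.approx(0.0)

    def test_hand_computed_nse(self):
        m = model_metrics([1, 2, 3, 4], [1, 2, 3, 5])
        assert m["nse"] == pytest.approx(1 - 1 / 5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            model_metrics([2, 2, 2], [1, 2, 3])


def _smooth_table(n, sigma, seed, countries=("a", "b", "c")):
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(-1, 1, n)
    x2 = rng.uniform(-1, 1, n)
    country = rng.choice(countries, n)
    offs = {c: 0.2 * i for i, c in enumerate(countries)}
    log_mean = 3.0 + 0.8 * np.sin(2 * x1) + 0.5 * x2 ** 2 \
        + np.array([offs[c] for c in country])
    y = np.exp(log_mean + rng.normal(0, sigma, n))
    return pd.DataFrame({"olsen_p_0_20": y, "x1": x1, "x2": x2,
                         "country": country, "log_mean": log_mean})


class TestOlsenPModel:
    def test_noiseless_recovery(self):
        df = _smooth_table(600, sigma=0.0, seed=3)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          augment_fraction=0.0).fit(split=0.7, seed=0)
        assert fit.metrics["r_squared"] > 99.0
        assert fit.metrics["nse"] > 0.99
        assert fit.smearing == pytest.approx(1.0, abs=1e-3)

    def test_heldout_r2_near_noise_ceiling(self):
        # analytic ceiling: var(signal) / (var(signal) + sigma^2) on log scale
        sigma = 0.4
        df = _smooth_table(3000, sigma=sigma, seed=5)
        signal_var = df["log_mean"].var()
        ceiling = 100 * signal_var / (signal_var + sigma ** 2)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          augment_fraction=0.0).fit(split=0.7, seed=0)
        assert abs(fit.metrics["r_squared"] - ceiling) < 8.0

    def test_smearing_correction_applied_to_predictions(self):
        df = _smooth_table(400, sigma=0.5, seed=8)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          augment_fraction=0.0).fit(split=None, seed=0)
        naive = fit.predict(df, correct_bias=False)
        corrected = fit.predict(df)
        np.testing.assert_allclose(corrected, fit.smearing * naive)
        assert fit.smearing > 1.0
        assert (corrected > 0).all()

    def test_unseen_country_routes_to_other(self):
        df = _smooth_table(400, sigma=0.2, seed=2)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          augment_fraction=0.05).fit(split=None, seed=0)
        new = df.head(5).copy()
        new["country"] = "zz_never_seen"
        via_other = new.copy()
        via_other["country"] = "other"
        np.testing.assert_allclose(fit.predict(new), fit.predict(via_other))

    def test_residuals_count_and_smearing_invariant(self):
        df = _smooth_table(300, sigma=0.3, seed=4)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          augment_fraction=0.0).fit(split=0.7, seed=1)
        assert len(fit.residuals) == len(fit.train_index)
        assert fit.smearing == pytest.approx(
            np.mean(np.exp(fit.residuals)))
        assert fit.smearing >= np.exp(fit.residuals.mean())

    def test_pca_block_enters_model(self):
        df = _smooth_table(500, sigma=0.2, seed=6)
        rng = np.random.default_rng(0)
        base = rng.normal(size=len(df))
        for j in range(4):  # correlated monthly-style block
            df[f"m{j}"] = base + rng.normal(0, 0.1, len(df))
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"],
                          pca_vars=[f"m{j}" for j in range(4)],
                          variance_target=0.95,
                          augment_fraction=0.0).fit(split=0.7, seed=0)
        assert fit.pca is not None
        assert fit.pca.n_retained < 4  # block is rank ~1
        assert fit.pca.cumulative_explained >= 0.95

    def test_summary_mentions_key_quantities(self):
        df = _smooth_table(300, sigma=0.3, seed=4)
        fit = OlsenPModel(df, smooth_terms=["x1", "x2"]).fit(split=0.7, seed=1)
        text = fit.summary()
        for token in ("smearing", "Shapiro", "R-squared", "NSE", "AIC"):
            assert token in text
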