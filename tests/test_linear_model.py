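import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

import grefde
from grefde.linear_model import (
    GenewiseFit,
    bh_adjust,
    ebayes_moderate,
    estimate_duplicate_correlation,
    fit_genewise,
    trigamma_inverse,
)
from grefde.spot_io import InputError
from conftest import make_normalized


STRAINS_15 = ["A"] * 5 + ["B"] * 5 + ["C"] * 5


class TestDuplicateCorrelation:
    def test_identical_duplicates_give_rho_near_one(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(500, 15, 1))
        cube = np.repeat(half, 2, axis=2)
        norm = make_normalized(cube, STRAINS_15)
        est = estimate_duplicate_correlation(norm)
        assert est.rho >= 0.99

    def test_independent_duplicates_give_rho_near_zero(self):
        rng = np.random.default_rng(1)
        cube = rng.normal(size=(1000, 15, 2))
        norm = make_normalized(cube, STRAINS_15)
        est = estimate_duplicate_correlation(norm)
        assert abs(est.rho) < 0.05

    def test_recovers_simulated_rho(self, norm_default):
        normalized, truth = norm_default
        est = estimate_duplicate_correlation(normalized)
        assert truth.rho == 0.6
        assert 0.5 <= est.rho <= 0.7

    def test_wrong_arity_rejected(self):
        cube = np.zeros((10, 3, 1))
        norm = make_normalized(cube, ["A", "A", "B"], duplicate_arity=1)
        with pytest.raises(InputError):
            estimate_duplicate_correlation(norm)


class TestFitGenewise:
    def test_noise_free_effects_recovered_exactly(self):
        cube = np.zeros((20, 15, 2))
        true_mc = np.linspace(-2, 2, 20)
        cube[:, 5:10, :] = true_mc[:, None, None]        # strain B
        cube[:, 10:15, :] = (true_mc * 0.5)[:, None, None]  # strain C
        norm = make_normalized(cube, STRAINS_15)
        fit = fit_genewise(norm, rho=0.0)
        np.testing.assert_allclose(fit.table["Mc_BvA"], true_mc, atol=1e-12)
        np.testing.assert_allclose(fit.table["Mc_CvA"], true_mc * 0.5, atol=1e-12)

    def test_matches_closed_form_ols(self):
        """rho=0, unit weights: equals per-gene ordinary regression."""
        rng = np.random.default_rng(2)
        cube = rng.normal(size=(50, 15, 2))
        norm = make_normalized(cube, STRAINS_15)
        fit = fit_genewise(norm, rho=0.0)
        X = np.zeros((30, 3))
        strain_idx = np.repeat([0] * 5 + [1] * 5 + [2] * 5, 2)
        X[np.arange(30), strain_idx] = 1.0
        for g in range(50):
            y = cube[g].ravel()
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = res[0] / (30 - 3)
            mc_bva = beta[1] - beta[0]
            se = math.sqrt(s2 * (1 / 10 + 1 / 10))
            assert fit.table["Mc_BvA"].iloc[g] == pytest.approx(mc_bva, abs=1e-10)
            assert fit.table["s2"].iloc[g] == pytest.approx(s2, abs=1e-10)
            assert fit.table["stderr_BvA"].iloc[g] == pytest.approx(se, abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        cube = rng.normal(size=(30, 15, 2))
        norm = make_normalized(cube, STRAINS_15)
        w = rng.uniform(0.2, 1.0, size=len(norm.spots))
        aw = pd.Series(1.0, index=[f"{s}{r}" for s in "ABC" for r in range(1, 6)])
        fit1 = fit_genewise(norm, spot_weights=w, array_weights=aw, rho=0.3)
        fit2 = fit_genewise(norm, spot_weights=2 * w, array_weights=aw, rho=0.3)
        np.testing.assert_allclose(fit1.table["Mc_BvA"], fit2.table["Mc_BvA"],
                                   atol=1e-12)
        np.testing.assert_allclose(fit1.table["stderr_BvA"],
                                   fit2.table["stderr_BvA"], atol=1e-12)

    def test_rho_zero_equals_duplicate_averaged_means(self):
        rng = np.random.default_rng(4)
        cube = rng.normal(size=(10, 15, 2))
        norm = make_normalized(cube, STRAINS_15)
        fit = fit_genewise(norm, rho=0.0)
        avg = cube.mean(axis=2)
        mc = avg[:, 5:10].mean(axis=1) - avg[:, :5].mean(axis=1)
        np.testing.assert_allclose(fit.table["Mc_BvA"], mc, atol=1e-12)

    def test_gene_with_insufficient_arrays_has_missing_contrast(self):
        cube = np.random.default_rng(5).normal(size=(5, 15, 2))
        cube[0, 5:9, :] = np.nan  # only one B array left for gene 0
        norm = make_normalized(cube, STRAINS_15)
        fit = fit_genewise(norm, rho=0.0)
        assert np.isnan(fit.table["Mc_BvA"].iloc[0])
        assert np.isfinite(fit.table["Mc_CvA"].iloc[0])
        assert np.isfinite(fit.table["Mc_BvA"].iloc[1:]).all()


def _fake_fit(s2, df, mc=None, unscaled=None):
    n = len(s2)
    table = pd.DataFrame(
        {
            "Mc_BvA": np.zeros(n) if mc is None else mc,
            "unscaled_BvA": np.ones(n) if unscaled is None else unscaled,
            "stderr_BvA": np.sqrt(s2),
            "s2": s2,
            "df_residual": df,
            "n_obs": df + 3,
        },
        index=[f"G{i}" for i in range(n)],
    )
    return GenewiseFit(table=table, contrasts=("BvA",), rho=0.0)


class TestEBayes:
    def test_d0_zero_limit_gives_ordinary_t(self):
        rng = np.random.default_rng(6)
        n = 200
        s2 = rng.chisquare(10, n) / 10 * 0.04
        mc = rng.normal(size=n)
        fit = _fake_fit(s2, np.full(n, 10.0), mc=mc)
        eb = ebayes_moderate(fit, d0=0, s02=0.04)
        np.testing.assert_allclose(eb.table["t_BvA"], mc / np.sqrt(s2), atol=1e-12)

    def test_d0_infinite_limit_pools_variances(self):
        rng = np.random.default_rng(7)
        n = 200
        s2 = rng.chisquare(10, n) / 10 * 0.04
        mc = rng.normal(size=n)
        fit = _fake_fit(s2, np.full(n, 10.0), mc=mc)
        eb = ebayes_moderate(fit, d0=math.inf, s02=0.04)
        assert (eb.table["s2_post"] == 0.04).all()
        # ordering equals |Mc| ordering under a common variance
        order_t = np.argsort(-np.abs(eb.table["t_BvA"].to_numpy()))
        order_mc = np.argsort(-np.abs(mc))
        np.testing.assert_array_equal(order_t, order_mc)

    def test_moderated_t_brackets_the_two_limits(self):
        rng = np.random.default_rng(8)
        n = 500
        sigma2 = 0.04 * 4 / rng.chisquare(4, n)
        s2 = sigma2 * rng.chisquare(10, n) / 10
        mc = rng.normal(size=n)
        fit = _fake_fit(s2, np.full(n, 10.0), mc=mc)
        eb = ebayes_moderate(fit)
        t_mod = np.abs(eb.table["t_BvA"].to_numpy())
        t_ord = np.abs(mc / np.sqrt(s2))
        t_pool = np.abs(mc / np.sqrt(eb.s02))
        lo = np.minimum(t_ord, t_pool) - 1e-9
        hi = np.maximum(t_ord, t_pool) + 1e-9
        assert ((t_mod >= lo) & (t_mod <= hi)).all()

    def test_hyperparameter_recovery(self):
        """s2 ~ s02*d0/chi2_d0 * chi2_df/df with d0=4, s02=0.04."""
        rng = np.random.default_rng(9)
        n, df, d0, s02 = 2000, 10, 4.0, 0.04
        sigma2 = s02 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        fit = _fake_fit(s2, np.full(n, float(df)))
        eb = ebayes_moderate(fit)
        assert 3.0 <= eb.d0 <= 5.5
        assert 0.032 <= eb.s02 <= 0.048

    def test_trigamma_inverse_round_trip(self):
        for x in (0.1, 0.5, 2.0, 10.0, 1e4):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestBHAdjust:
    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=40),
    )
    def test_matches_brute_force_step_up(self, p):
        p = np.array(p)
        got = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        for i in range(m):
            rank_i = int(np.flatnonzero(order == i)[0]) + 1
            candidates = [
                min(p[order[j - 1]] * m / j, 1.0)
                for j in range(rank_i, m + 1)
            ]
            brute[i] = min(candidates)
        np.testing.assert_allclose(got, brute, atol=1e-12)
        assert (got >= p - 1e-15).all() and (got <= 1.0 + 1e-15).all()

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 200))
            np.testing.assert_allclose(
                bh_adjust(p), mt.multipletests(p, method="fdr_bh")[1], atol=1e-12
            )
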