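import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import grefde
from grefde.normalization import (
    DegenerateGroupError,
    InsufficientDataError,
    compute_m_a,
    global_loess,
    loess_fit,
    normalize_array,
    print_tip_weighted_median,
    weighted_median,
)
from grefde.spot_io import InputError


class TestComputeMA:
    def test_basic_arithmetic(self):
        m, a = compute_m_a(800.0, 200.0)
        assert m == pytest.approx(2.0)
        assert a == pytest.approx(0.5 * np.log2(160000.0))

    def test_symmetry_equal_channels(self):
        m, _ = compute_m_a(500.0, 500.0)
        assert m == 0.0

    def test_background_subtraction_floor(self):
        m, _ = compute_m_a(100.0, 400.0, bg_cdna=150.0, bg_gdna=0.0,
                           background_mode="subtract", eps=0.5)
        assert m == pytest.approx(np.log2(0.5 / 400.0))

    def test_zero_foreground_is_missing_under_none(self):
        m, a = compute_m_a(0.0, 100.0)
        assert np.isnan(m) and np.isnan(a)

    def test_negative_intensity_rejected(self):
        with pytest.raises(InputError):
            compute_m_a(-1.0, 100.0)


class TestWeightedMedian:
    def test_equal_weights_centres_ordinary_median(self):
        out = print_tip_weighted_median([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_location_equivariance_constant_input(self):
        out = print_tip_weighted_median([4.2] * 5)
        np.testing.assert_allclose(out, 0.0)

    def test_cumulative_weight_rule(self):
        # first value already carries 99% of the weight -> median 0
        out = print_tip_weighted_median([0.0, 10.0], [0.99, 0.01])
        np.testing.assert_allclose(out, [0.0, 10.0])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DegenerateGroupError):
            weighted_median(np.array([1.0, 2.0]), np.array([0.0, 0.0]))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50),
                st.floats(0.01, 5.0),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_brute_force_definition(self, pairs):
        """Smallest value whose cumulative normalized weight reaches 0.5."""
        values = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs])
        got = weighted_median(values, weights)
        order = np.argsort(values, kind="stable")
        cum = 0.0
        total = weights.sum()
        expected = None
        for i in order:
            cum += weights[i]
            if cum / total >= 0.5:
                expected = values[i]
                break
        assert got == expected
        # centring property: weighted median of centred values is ~0
        centred = print_tip_weighted_median(values, weights)
        assert abs(weighted_median(centred, weights)) < 1e-12


class TestLoess:
    def test_flat_null_fit_is_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, size=2000)
        m = rng.normal(0, 0.25, size=2000)
        fitted = loess_fit(a, m, span=0.3)
        assert np.abs(fitted).mean() < 0.02

    def test_detrending_recovers_smooth_curve(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, size=2000)
        m = 0.3 * np.sin(a / 2.0) + 0.2
        mg = global_loess(m, a, span=0.3)
        assert np.abs(mg).max() < 0.05

    def test_constant_shift_absorbed(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, size=500)
        mg = global_loess(np.full(500, 1.7), a, span=0.5)
        np.testing.assert_allclose(mg, 0.0, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            loess_fit(np.arange(5.0), np.arange(5.0))

    def test_matches_statsmodels_lowess_at_unit_weights(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 10, size=500))
        m = np.sin(a) + rng.normal(0, 0.1, size=500)
        ours = loess_fit(a, m, span=0.4, iterations=0, max_eval=500)
        ref = sm.nonparametric.lowess(m, a, frac=0.4, it=0, return_sorted=False)
        assert np.mean(np.abs(ours - ref)) < 0.01

    def test_missing_values_propagate(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(6, 14, size=100)
        m = rng.normal(0, 0.1, size=100)
        m[3] = np.nan
        mg = global_loess(m, a, span=0.5)
        assert np.isnan(mg[3]) and np.isfinite(np.delete(mg, 3)).all()


def _synthetic_array(n=2000, seed=0, tip_offsets=(0.5, -0.5), dye=True, m_sd=0.2):
    rng = np.random.default_rng(seed)
    level = rng.lognormal(7.0 * np.log(2), 1.0, size=n)
    a_clean = np.log2(level)
    a_std = (a_clean - a_clean.mean()) / a_clean.std()
    block = np.repeat(np.arange(1, len(tip_offsets) + 1), n // len(tip_offsets))
    m = rng.normal(0, m_sd, size=n) + np.asarray(tip_offsets)[block - 1]
    if dye:
        m = m + 0.2 + 0.1 * a_std + 0.025 * a_std**3
    fg_gdna = level
    fg_cdna = level * 2.0**m
    return pd.DataFrame(
        {
            "array_id": "A1",
            "block": block,
            "row": np.arange(n) + 1,
            "col": 1,
            "gene_id": [f"G{i:04d}" for i in range(n)],
            "duplicate_index": 1,
            "fg_cdna": fg_cdna,
            "bg_cdna": 10.0,
            "fg_gdna": fg_gdna,
            "bg_gdna": 10.0,
        }
    )


class TestNormalizeArray:
    def test_removes_tip_offsets_and_dye_bias(self):
        spots = _synthetic_array()
        na = normalize_array(spots)
        # per-tip weighted median of the tip-corrected M is exactly 0
        for b, sub in na.spots.groupby("block"):
            assert abs(weighted_median(sub["M_tip"].to_numpy(),
                                       np.ones(len(sub)))) < 1e-9
            # after loess the per-tip centring still holds approximately
            assert abs(np.median(sub["Mg"])) < 0.05
        # residual intensity trend is flat
        slope = np.polyfit(na.spots["A"], na.spots["Mg"], 1)[0]
        assert abs(slope) < 0.02
        # the recorded tip medians reflect the injected offsets
        meds = na.tip_medians
        assert meds.loc[1] - meds.loc[2] == pytest.approx(1.0, abs=0.05)

    def test_idempotent_on_already_normalized_data(self):
        spots = _synthetic_array(seed=5, tip_offsets=(0.0, 0.0), dye=False,
                                 m_sd=0.1)
        na1 = normalize_array(spots)
        renorm = spots.copy()
        renorm["fg_cdna"] = renorm["fg_gdna"] * 2.0 ** na1.spots["Mg"].to_numpy()
        na2 = normalize_array(renorm)
        assert np.abs(na2.spots["Mg"].to_numpy()
                      - na1.spots["Mg"].to_numpy()).max() < 0.05

    def test_all_missing_tip_raises_naming_block(self):
        spots = _synthetic_array(n=200, tip_offsets=(0.0, 0.0))
        spots.loc[spots["block"] == 2, "fg_cdna"] = 0.0
        with pytest.raises(DegenerateGroupError, match="2"):
            normalize_array(spots)


def test_normalized_set_per_array_mean_near_zero(norm_default):
    """After normalization each array's mean Mg is close to 0."""
    normalized, _ = norm_default
    means = normalized.spots.groupby("array_id")["Mg"].mean()
    assert np.abs(means).max() < 0.06


def test_normalization_is_per_array(sim_default):
    """Dropping other arrays does not change one array's normalized values."""
    _, arrayset, _ = sim_default
    aid = arrayset.array_ids[0]
    sub = arrayset.spots[arrayset.spots["array_id"] == aid]
    alone = normalize_array(sub)
    full = grefde.normalize_set(arrayset)
    joint = full.spots[full.spots["array_id"] == aid]
    np.testing.assert_allclose(
        alone.spots["Mg"].to_numpy(), joint["Mg"].to_numpy(), atol=1e-12
    )
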