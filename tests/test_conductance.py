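"""Unit tests for pixel pairing, slope (Rd/Rc) estimation and Gd/Gc."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdassay.image_analysis import DffMap, ShapeMask
from vsdassay.conductance import (
    PixelPairSet,
    SlopeModel,
    dff_histogram,
    fit_slope,
    pair_pixels,
    rectification_index,
    to_conductance,
    to_resistance,
    well_conductance,
)


def _dff(values, mask=None, shape=(40, 40)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        n = len(values)
        coords = np.column_stack([np.arange(n) // shape[1], np.arange(n) % shape[1]])
        mask = ShapeMask(coords, shape)
    return DffMap(mask, values)


def _pairs(x, y):
    return PixelPairSet(np.asarray(x, float), np.asarray(y, float))


def _sym_x(n, lo=0.005, hi=0.05, seed=0):
    rng = np.random.default_rng(seed)
    mag = rng.uniform(lo, hi, n)
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return mag * sign


class TestPairPixels:
    def test_identity_maps_give_y_equals_x(self):
        v = np.linspace(-0.05, 0.05, 100)
        m = _dff(v).mask
        pairs = pair_pixels(DffMap(m, v), DffMap(m, v.copy()))
        assert np.array_equal(pairs.x, pairs.y)

    def test_exclusions_union(self):
        v = np.linspace(-0.05, 0.05, 100)
        m = _dff(v).mask
        a, b = v.copy(), v.copy()
        a[3] = np.nan
        b[7] = np.nan
        pairs = pair_pixels(DffMap(m, a), DffMap(m, b))
        assert len(pairs) == 98

    def test_mask_mismatch_rejected(self):
        a = _dff(np.zeros(50))
        other_mask = ShapeMask(a.mask.coords[:-1], a.mask.shape)
        b = DffMap(other_mask, np.zeros(49))
        with pytest.raises(ValueError, match="mask mismatch"):
            pair_pixels(a, b)


class TestSlopeFit:
    def test_exact_line_half_slope(self):
        x = _sym_x(200)
        fit = fit_slope(_pairs(x, 0.5 * x))
        assert fit.slope_all == pytest.approx(0.5, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_control_unity_slope(self):
        x = _sym_x(200)
        fit = fit_slope(_pairs(x, x))
        assert fit.slope_all == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_within_3_stderr_of_ols_closed_form(self):
        rng = np.random.default_rng(5)
        x = _sym_x(10_000, seed=5)
        y = 0.3 * x + rng.normal(0, 0.1 * np.abs(x))
        fit = fit_slope(_pairs(x, y))
        # independent closed-form OLS through the origin
        expected = float(x @ y / (x @ x))
        assert fit.slope_all == pytest.approx(expected, rel=1e-12)
        assert abs(fit.slope_all - 0.3) < 3 * fit.stderr

    def test_deadband_removes_uninformative_pairs(self):
        x = np.concatenate([_sym_x(100), np.full(50, 1e-4)])
        y = 0.5 * x
        fit = fit_slope(_pairs(x, y), x_deadband=0.002)
        assert fit.n_pairs == 100

    def test_insufficient_pairs_rejected(self):
        x = _sym_x(30)
        with pytest.raises(ValueError, match="insufficient"):
            fit_slope(_pairs(x, x))

    def test_all_in_deadband_rejected(self):
        x = np.full(100, 1e-4) * np.where(np.arange(100) % 2 == 0, 1, -1)
        with pytest.raises(ValueError, match="insufficient"):
            fit_slope(_pairs(x, x))

    def test_split_slopes_by_sign(self):
        x = _sym_x(400)
        y = np.where(x < 0, 0.2 * x, 0.5 * x)
        fit = fit_slope(_pairs(x, y))
        assert fit.slope_neg == pytest.approx(0.2, abs=1e-12)
        assert fit.slope_pos == pytest.approx(0.5, abs=1e-12)
        assert rectification_index(fit) == pytest.approx(2.5)

    def test_robust_variant_resists_outliers(self):
        x = _sym_x(500)
        y = 0.5 * x
        y[:25] += 0.5  # gross outliers
        robust = fit_slope(_pairs(x, y), robust=True)
        plain = fit_slope(_pairs(x, y))
        assert abs(robust.slope_all - 0.5) < abs(plain.slope_all - 0.5)

    @given(scale=st.floats(0.01, 100), slope=st.floats(0.1, 5))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale, slope):
        x = _sym_x(200)
        fit1 = fit_slope(_pairs(x, slope * x))
        fit2 = fit_slope(_pairs(scale * x, scale * slope * x), x_deadband=0.0)
        assert fit2.slope_all == pytest.approx(fit1.slope_all, rel=1e-9)

    def test_summary_mentions_slope_and_conductance(self):
        x = _sym_x(200)
        s = fit_slope(_pairs(x, 0.5 * x)).summary()
        assert "Rd/Rc" in s and "Gd/Gc" in s


class TestConductance:
    @pytest.mark.parametrize("slope,expected", [(0.5, 2.0), (1.0, 1.0), (0.2, 5.0)])
    def test_reciprocal(self, slope, expected):
        x = _sym_x(200)
        fit = fit_slope(_pairs(x, slope * x))
        assert to_conductance(fit) == pytest.approx(expected, rel=1e-9)

    def test_nonphysical_slope_rejected(self):
        with pytest.raises(ValueError, match="nonphysical"):
            to_conductance(-0.1)

    def test_roundtrip_identity(self):
        for g in (0.25, 1.0, 4.0):
            assert to_resistance(to_conductance(g)) == pytest.approx(g)

    def test_well_aggregate_mean_and_se(self):
        x = _sym_x(200)
        fits = [fit_slope(_pairs(x, s * x)) for s in (0.5, 0.4, 0.25)]
        pt = well_conductance(fits, concentration=1e-6, well_id="A01")
        vals = np.array([2.0, 2.5, 4.0])
        assert pt.gd_gc == pytest.approx(vals.mean())
        assert pt.se == pytest.approx(vals.std(ddof=1) / np.sqrt(3))
        assert pt.n_areas == 3


class TestDffHistogram:
    def test_all_zeros_single_central_bin(self):
        counts, edges = dff_histogram(_dff(np.zeros(64)), bin_width=0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert counts.sum() == 64
        assert counts[np.argmin(np.abs(centers))] == 64

    def test_counts_sum_to_included_pixels(self):
        v = np.linspace(-0.04, 0.04, 100)
        v[0] = np.nan
        counts, _ = dff_histogram(_dff(v), bin_width=0.005)
        assert counts.sum() == 99

    def test_drug_narrows_distribution(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(0, 0.03, 2000)
        test = 0.2 * ref  # saturating drug: responses shrink by the slope
        c_ref, e = dff_histogram(ref, 0.005)
        c_test, _ = dff_histogram(test, 0.005)
        def var(c, e):
            mid = 0.5 * (e[:-1] + e[1:])
            return np.sum(c * mid**2) / c.sum()
        assert var(c_test, _) < var(c_ref, e)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            dff_histogram(_dff(np.zeros(10)), bin_width=0.0)
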