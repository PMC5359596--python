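"""Unit tests for registration, binning, shape mask and dF/F computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdassay.image_analysis import (
    AnalysisError,
    ShapeMask,
    bin_image,
    build_shape_mask,
    compute_dff,
    register,
    translate,
)


def _textured_frame(rng, shape=(64, 64)):
    return rng.uniform(100, 1000, shape)


class TestRegister:
    def test_identity(self):
        rng = np.random.default_rng(0)
        f = _textured_frame(rng)
        assert register(f, f, 5) == (0, 0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(1)
        f = _textured_frame(rng, (96, 96))
        shifted = np.roll(np.roll(f, 3, axis=0), -2, axis=1)
        assert register(f, shifted, 5) == (3, -2)

    def test_zero_window_degenerate(self):
        rng = np.random.default_rng(2)
        f = _textured_frame(rng)
        assert register(f, np.roll(f, 2, axis=0), 0) == (0, 0)

    def test_flat_frame_unregistrable(self):
        flat = np.full((32, 32), 7.0)
        with pytest.raises(AnalysisError, match="unregistrable"):
            register(flat, flat, 3)

    def test_translate_inverts_integer_shift_away_from_edges(self):
        rng = np.random.default_rng(3)
        f = _textured_frame(rng, (64, 64))
        shifted = translate(f, (2, -3))
        back = translate(shifted, (-2, 3))
        assert np.array_equal(back[5:-5, 5:-5], f[5:-5, 5:-5])

    @given(dr=st.integers(-4, 4), dc=st.integers(-4, 4), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_shift_recovery(self, dr, dc, seed):
        rng = np.random.default_rng(seed)
        f = _textured_frame(rng, (80, 80))
        shifted = np.roll(np.roll(f, dr, axis=0), dc, axis=1)
        assert register(f, shifted, 5) == (dr, dc)


class TestBinImage:
    def test_constant_image_preserved(self):
        f = np.full((32, 32), 100.0)
        out = bin_image(f, 4)
        assert out.shape == (8, 8)
        assert np.allclose(out, 100.0)

    def test_factor_one_identity(self):
        f = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(bin_image(f, 1), f)

    def test_block_mean(self):
        f = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert bin_image(f, 2) == pytest.approx(np.array([[2.5]]))

    def test_edge_cropping(self):
        f = np.ones((10, 7))
        assert bin_image(f, 4).shape == (2, 1)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            bin_image(np.ones((8, 8)), 0)

    def test_binning_reduces_flat_noise_variance_16x(self):
        rng = np.random.default_rng(7)
        f = rng.poisson(10000, size=(400, 400)).astype(float)
        v_raw = f.var()
        v_bin = bin_image(f, 4).var()
        assert v_raw / v_bin == pytest.approx(16.0, rel=0.15)


def _annulus_frame(outer=20, width=3, shape=(96, 96), center=(48, 48), hi=1000.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    frame = np.full(shape, 10.0)
    ring = (dist > outer - width) & (dist <= outer)
    frame[ring] = hi
    frame[dist <= outer - width] = 200.0
    return frame, ring


class TestBuildShapeMask:
    def test_covers_true_ring_within_foreground(self):
        frame, ring = _annulus_frame()
        mask = build_shape_mask(frame, object_threshold=0.2, ring_depth=3)
        got = mask.to_array()
        # ground-truth ring membership from the generating geometry
        assert (got & ring).sum() >= 0.9 * ring.sum()
        fg = frame > 0.2 * np.percentile(frame, 99.5)
        assert np.all(fg[got])

    def test_uniform_dark_frame_has_no_cells(self):
        with pytest.raises(AnalysisError, match="no cells"):
            build_shape_mask(np.full((64, 64), 5.0))

    def test_deep_ring_returns_entire_object(self):
        frame, _ = _annulus_frame()
        shallow = build_shape_mask(frame, ring_depth=2)
        full = build_shape_mask(frame, ring_depth=30)
        assert len(full) >= len(shallow)
        fg = frame > 0.2 * np.percentile(frame, 99.5)
        assert len(full) == fg.sum()

    def test_small_components_dropped(self):
        frame, _ = _annulus_frame()
        frame[2, 2] = 1000.0  # single-pixel debris
        mask = build_shape_mask(frame, min_component=8)
        assert (2, 2) not in {tuple(c) for c in mask.coords}

    def test_provenance_recorded(self):
        frame, _ = _annulus_frame()
        mask = build_shape_mask(frame, object_threshold=0.3, ring_depth=2)
        assert mask.provenance["object_threshold"] == 0.3
        assert mask.provenance["ring_depth"] == 2


class TestComputeDff:
    @pytest.fixture
    def mask(self):
        frame, _ = _annulus_frame()
        return build_shape_mask(frame)

    @pytest.fixture
    def resting(self):
        frame, _ = _annulus_frame()
        return frame

    def test_no_response_all_zero(self, resting, mask):
        out = compute_dff(resting, resting.copy(), mask)
        assert np.allclose(out.values, 0.0)

    def test_arithmetic(self, mask):
        pre = np.full(mask.shape, 100.0)
        plat = np.full(mask.shape, 95.0)
        out = compute_dff(pre, plat, mask)
        assert np.allclose(out.values, -0.05)

    def test_low_resting_pixels_excluded_and_counted(self, resting, mask):
        pre = resting.copy()
        r, c = mask.coords[0]
        pre[r, c] = 1.0  # below floor
        out = compute_dff(pre, resting, mask)
        assert out.n_excluded == 1
        assert not np.isfinite(out.values[0])

    def test_implausible_values_flagged(self, resting, mask):
        plat = resting * 2.0  # dF/F = 1 everywhere, beyond the window
        with pytest.raises(AnalysisError, match="unusable"):
            compute_dff(resting, plat, mask)

    def test_gain_invariance(self, resting, mask):
        plat = resting * 0.97
        a = compute_dff(resting, plat, mask)
        b = compute_dff(3.0 * resting, 3.0 * plat, mask)
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestShapeMaskContainer:
    def test_out_of_bounds_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ShapeMask(np.array([[70, 2]]), (64, 64))

    def test_mask_export_roundtrip(self, tmp_path):
        import tifffile

        frame, _ = _annulus_frame()
        mask = build_shape_mask(frame)
        out = tmp_path / "mask.tif"
        mask.save(out)
        img = tifffile.imread(out)
        assert np.array_equal(img > 0, mask.to_array())

    def test_same_support(self):
        coords = np.array([[1, 2], [3, 4]])
        a = ShapeMask(coords, (8, 8))
        b = ShapeMask(coords.copy(), (8, 8))
        c = ShapeMask(np.array([[1, 2]]), (8, 8))
        assert a.same_support(b)
        assert not a.same_support(c)
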