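"""Frame-pair processing: registration, binning, shape mask, dF/F_R maps.

The pipeline order is deliberate: integer-pixel registration on raw frames,
then non-overlapping binning of raw counts (averaging counts before taking
ratios is the lower-variance order for shot-noise-dominated images), then a
membrane-ring shape mask built once from the reference resting frame and
reused for the test passage so that pixels pair one-to-one across passages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AnalysisError",
    "ShapeMask",
    "DffMap",
    "register",
    "translate",
    "bin_image",
    "build_shape_mask",
    "compute_dff",
]


class AnalysisError(RuntimeError):
    """An area could not be analyzed (unregistrable, no cells, unusable)."""


@dataclass(frozen=True)
class ShapeMask:
    """Analyzed pixels in binned-image space: cell foreground restricted to
    a ring at the membrane region.  Coordinates are 0-based (row, col),
    stored sorted for deterministic pairing."""

    coords: np.ndarray  # (n, 2) int
    shape: tuple[int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords)
        if c.size == 0:
            raise AnalysisError("insufficient mask")
        if c.min() < 0 or np.any(c.max(axis=0) >= np.asarray(self.shape)):
            raise ValueError("mask coordinates outside image bounds")

    def __len__(self) -> int:
        return len(self.coords)

    def to_array(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[self.coords[:, 0], self.coords[:, 1]] = True
        return out

    def same_support(self, other: "ShapeMask") -> bool:
        return self.shape == other.shape and np.array_equal(
            self.coords, other.coords
        )

    def save(self, path) -> None:
        """Export the mask as a binary image (0/255 uint8 TIFF) for inspection."""
        import tifffile

        tifffile.imwrite(
            path, self.to_array().astype(np.uint8) * 255, photometric="minisblack"
        )


@dataclass(frozen=True)
class DffMap:
    """Per-pixel dF/F_R over a shape mask; NaN marks excluded pixels."""

    mask: ShapeMask
    values: np.ndarray  # (n,), aligned with mask.coords
    passage: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if len(self.values) != len(self.mask):
            raise ValueError("values must align with the mask coordinates")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def register(
    reference_frame: np.ndarray,
    test_frame: np.ndarray,
    max_shift: int = 5,
) -> tuple[int, int]:
    """Integer shift (drow, dcol) of ``test_frame`` relative to the reference.

    Maximizes the normalized cross-correlation (Pearson r on the overlap)
    over all integer shifts within ±max_shift; ties broken toward the
    smaller shift, lexicographically on (|dr|+|dc|, dr, dc).  Translating the
    test frame by the negated shift aligns it to the reference.
    """
    ref = np.asarray(reference_frame, dtype=float)
    tst = np.asarray(test_frame, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("frames must have the same shape")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if np.ptp(ref) == 0 or np.ptp(tst) == 0:
        raise AnalysisError("unregistrable: flat frame")
    if max_shift == 0:
        return (0, 0)

    shifts = [
        (dr, dc)
        for dr in range(-max_shift, max_shift + 1)
        for dc in range(-max_shift, max_shift + 1)
    ]
    shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]))
    best, best_r = (0, 0), -np.inf
    h, w = ref.shape
    for dr, dc in shifts:
        # overlap of ref with test translated by (-dr, -dc)
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r1 - r0 < 2 or c1 - c0 < 2:
            continue
        a = ref[r0:r1, c0:c1].ravel()
        b = tst[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(a @ a) * np.sqrt(b @ b)
        if denom == 0:
            continue
        r = (a @ b) / denom
        if r > best_r + 1e-12:
            best, best_r = (dr, dc), r
    return best


def translate(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer translation with edge replication (exact pixel relocation)."""
    return ndimage.shift(
        np.asarray(frame, dtype=float), shift, order=0, mode="nearest"
    )


def bin_image(frame: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping factor x factor blocks of raw counts.

    Trailing rows/columns that do not fill a block are cropped.
    """
    if factor <= 0:
        raise ValueError("binning factor must be >= 1")
    f = np.asarray(frame, dtype=float)
    if factor == 1:
        return f.copy()
    h, w = (f.shape[0] // factor) * factor, (f.shape[1] // factor) * factor
    if h == 0 or w == 0:
        raise ValueError("frame smaller than one bin")
    return (
        f[:h, :w]
        .reshape(h // factor, factor, w // factor, factor)
        .mean(axis=(1, 3))
    )


def build_shape_mask(
    resting_frame: np.ndarray,
    object_threshold: float = 0.2,
    ring_depth: int = 3,
    smooth_size: int = 3,
    min_component: int = 8,
    min_mask_pixels: int = 50,
) -> ShapeMask:
    """Membrane-region mask from a (binned) resting frame.

    Pixels enter the mask when they (1) belong to the cell — intensity above
    ``object_threshold`` times a robust maximum (99.5th percentile) after
    light uniform smoothing — and (2) lie within ``ring_depth`` pixels of
    the object boundary (difference with the morphologically eroded
    foreground).  Components smaller than ``min_component`` pixels are
    discarded as debris.
    """
    if not 0 < object_threshold < 1:
        raise ValueError("object_threshold must be in (0, 1)")
    if ring_depth < 1:
        raise ValueError("ring_depth must be >= 1")
    frame = np.asarray(resting_frame, dtype=float)
    smoothed = ndimage.uniform_filter(frame, size=smooth_size)
    robust_max = float(np.percentile(smoothed, 99.5))
    # the unsmoothed frame must clear the threshold too: smoothing alone
    # dilates the object by ~1 px and would admit background pixels whose
    # dF/F carries no signal and large noise
    fg = (smoothed > object_threshold * robust_max) & (
        frame > object_threshold * robust_max
    )
    # require contrast over the frame floor so a uniform frame has no cells
    fg &= smoothed > np.min(smoothed) + 1e-12
    if not fg.any():
        raise AnalysisError("no cells detected")
    labels, n = ndimage.label(fg)
    if n:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component) + 1
        fg = np.isin(labels, keep)
    if not fg.any():
        raise AnalysisError("no cells detected")
    eroded = ndimage.binary_erosion(fg, iterations=ring_depth, border_value=0)
    ring = fg & ~eroded
    if ring.sum() < min_mask_pixels:
        raise AnalysisError("insufficient mask")
    coords = np.argwhere(ring)
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    return ShapeMask(
        coords,
        frame.shape,
        provenance=dict(
            object_threshold=object_threshold,
            ring_depth=ring_depth,
            smooth_size=smooth_size,
            min_component=min_component,
            robust_max=robust_max,
        ),
    )


def compute_dff(
    pre: np.ndarray,
    plateau: np.ndarray,
    mask: ShapeMask,
    f_floor: float = 50.0,
    plausibility: float = 0.5,
    passage: str = "",
    max_excluded_fraction: float = 0.5,
) -> DffMap:
    """Per-pixel dF/F_R = (F_S - F_R) / F_R over the shape mask.

    Pixels with resting counts at or below ``f_floor`` (ratio undefined) or
    with |dF/F| beyond the plausibility window (physically implausible for a
    fast dye at these drives) are excluded (NaN) and counted; an area with
    more than half its mask excluded is rejected as unusable.
    """
    pre = np.asarray(pre, dtype=float)
    plateau = np.asarray(plateau, dtype=float)
    if pre.shape != mask.shape or plateau.shape != mask.shape:
        raise ValueError("frames do not match the mask geometry")
    fr = pre[mask.coords[:, 0], mask.coords[:, 1]]
    fs = plateau[mask.coords[:, 0], mask.coords[:, 1]]
    values = np.full(len(mask), np.nan)
    ok = fr > f_floor
    values[ok] = (fs[ok] - fr[ok]) / fr[ok]
    implausible = np.abs(values) > plausibility
    values[implausible] = np.nan
    n_excluded = int(np.sum(~np.isfinite(values)))
    if n_excluded > max_excluded_fraction * len(mask):
        raise AnalysisError("unusable area: too many excluded pixels")
    return DffMap(mask, values, passage=passage, n_excluded=n_excluded)
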