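"""Rd/Rc and Gd/Gc estimation from paired per-pixel dF/F_R measurements.

Because the same test current is applied in both passages, Ohm's law makes
the test-passage response of each pixel proportional to the reference
response, with proportionality constant Rd/Rc (drug-to-control resistance
ratio).  The estimator is therefore a through-origin regression of the test
dF/F on the reference dF/F over all mask pixels of a sampling area; the
reciprocal of the slope is the conductance ratio Gd/Gc.  Splitting the
regression by the sign of the reference response (depolarizing versus
hyperpolarizing membrane) exposes rectification as unequal slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_analysis import DffMap

__all__ = [
    "PixelPairSet",
    "SlopeFit",
    "SlopeModel",
    "ConductancePoint",
    "pair_pixels",
    "fit_slope",
    "rectification_index",
    "to_conductance",
    "to_resistance",
    "dff_histogram",
    "well_conductance",
]

#: Fewest pairs for a usable whole-area slope / a usable split slope.
MIN_PAIRS = 50
MIN_SPLIT_PAIRS = 20


@dataclass(frozen=True)
class PixelPairSet:
    """Ordered (reference, test) dF/F_R pairs, one per common mask pixel."""

    x: np.ndarray  # reference passage dFc/FRc
    y: np.ndarray  # test passage dFd/FRd
    well_id: str = ""
    area_id: int = 0
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must pair one-to-one")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("pairs must be finite")

    def __len__(self) -> int:
        return len(self.x)


def pair_pixels(ref: DffMap, test: DffMap) -> PixelPairSet:
    """Pair reference and test dF/F values recorded at the same pixels.

    Both maps must share one mask support; pixels excluded in either passage
    are dropped from both.
    """
    if not ref.mask.same_support(test.mask):
        raise ValueError("mask mismatch between reference and test passages")
    keep = ref.valid & test.valid
    return PixelPairSet(ref.values[keep], test.values[keep])


def _origin_ls(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Through-origin least squares slope and its standard error."""
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    dof = max(len(x) - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / sxx))
    return slope, stderr


def _free_ls(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = max(len(x) - 2, 1)
    ssr = float(res[0]) if res.size else float(np.sum((y - A @ coef) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    return float(coef[0]), float(np.sqrt(ssr / dof / sxx))


def _theil_sen_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Through-origin Theil–Sen: median of per-pair ratios y/x."""
    return float(np.median(y / x))


@dataclass(frozen=True)
class SlopeFit:
    """Results of the paired-scatter regression for one sampling area.

    ``slope_all`` estimates Rd/Rc; ``slope_neg``/``slope_pos`` are the same
    regression restricted to negative / positive reference responses (for a
    dye that dims on depolarization these are the depolarizing and
    hyperpolarizing membrane sides respectively); either is None when its
    side is underpopulated.
    """

    slope_all: float
    stderr: float
    n_pairs: int
    slope_neg: float | None = None
    slope_pos: float | None = None
    intercept: float | None = None
    method: str = "ols"

    @property
    def rd_rc(self) -> float:
        return self.slope_all

    @property
    def gd_gc(self) -> float:
        return to_conductance(self)

    def summary(self) -> str:
        lines = [
            "Paired-scatter slope fit (test vs reference dF/F_R)",
            f"  method        : {self.method}, through origin"
            + ("" if self.intercept is None else " + free intercept"),
            f"  n pairs       : {self.n_pairs}",
            f"  Rd/Rc (slope) : {self.slope_all:.6g} +/- {self.stderr:.2g}",
            f"  Gd/Gc (1/slope): {self.gd_gc:.6g}",
        ]
        if self.slope_neg is not None and self.slope_pos is not None:
            lines.append(
                f"  split slopes  : neg {self.slope_neg:.6g}, "
                f"pos {self.slope_pos:.6g} "
                f"(rectification index {self.slope_pos / self.slope_neg:.4g})"
            )
        return "\n".join(lines)


class SlopeModel:
    """Through-origin regression model for a :class:`PixelPairSet`.

    Parameters
    ----------
    pairs : the per-pixel (reference, test) response pairs of one area.
    x_deadband : pairs with |reference dF/F| below this carry no slope
        information (unresponsive membrane perpendicular to the field) and
        are dropped before fitting.
    robust : use the through-origin Theil–Sen estimator (median of y/x)
        instead of least squares.
    free_intercept : diagnostic variant with an unconstrained intercept;
        the Ohm relation itself has none.
    """

    def __init__(
        self,
        pairs: PixelPairSet,
        x_deadband: float = 0.002,
        min_pairs: int = MIN_PAIRS,
        robust: bool = False,
        free_intercept: bool = False,
    ) -> None:
        self.pairs = pairs
        self.x_deadband = x_deadband
        self.min_pairs = min_pairs
        self.robust = robust
        self.free_intercept = free_intercept

    def fit(self) -> SlopeFit:
        keep = np.abs(self.pairs.x) >= self.x_deadband
        x, y = self.pairs.x[keep], self.pairs.y[keep]
        if len(x) < self.min_pairs:
            raise ValueError("insufficient responsive pixels")
        intercept = None
        if self.robust:
            slope = _theil_sen_origin(x, y)
            _, stderr = _origin_ls(x, y)
            method = "theil-sen"
        elif self.free_intercept:
            slope, stderr = _free_ls(x, y)
            intercept = float(np.mean(y) - slope * np.mean(x))
            method = "ols"
        else:
            slope, stderr = _origin_ls(x, y)
            method = "ols"

        def side(sel):
            if np.sum(sel) < MIN_SPLIT_PAIRS:
                return None
            if self.robust:
                return _theil_sen_origin(x[sel], y[sel])
            return _origin_ls(x[sel], y[sel])[0]

        return SlopeFit(
            slope_all=slope,
            stderr=stderr,
            n_pairs=int(len(x)),
            slope_neg=side(x < 0),
            slope_pos=side(x > 0),
            intercept=intercept,
            method=method,
        )


def fit_slope(pairs: PixelPairSet, x_deadband: float = 0.002, **kw) -> SlopeFit:
    """Convenience wrapper: ``SlopeModel(pairs, x_deadband, **kw).fit()``."""
    return SlopeModel(pairs, x_deadband=x_deadband, **kw).fit()


def rectification_index(fit: SlopeFit) -> float | None:
    """Ratio of hyperpolarizing-side to depolarizing-side slope.

    1 for an ohmic channel; > 1 when the drug reduces resistance more
    strongly on the depolarizing side (outward-rectification signature).
    None when either side is underpopulated.
    """
    if fit.slope_neg is None or fit.slope_pos is None:
        return None
    return fit.slope_pos / fit.slope_neg


def to_conductance(fit: SlopeFit | float) -> float:
    """Gd/Gc = 1 / (Rd/Rc)."""
    slope = fit.slope_all if isinstance(fit, SlopeFit) else float(fit)
    if slope <= 0:
        raise ValueError("nonphysical slope: Rd/Rc must be > 0")
    return 1.0 / slope


def to_resistance(gd_gc: float) -> float:
    """Inverse of :func:`to_conductance`."""
    if gd_gc <= 0:
        raise ValueError("nonphysical conductance ratio")
    return 1.0 / gd_gc


def dff_histogram(
    dff: DffMap | np.ndarray, bin_width: float = 0.005
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency distribution of dF/F values, binned symmetrically about 0.

    Returns ``(counts, edges)`` with 0 at the center of the middle bin;
    counts sum to the number of included (finite) pixels.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = dff.values if isinstance(dff, DffMap) else np.asarray(dff, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty dF/F map")
    m = int(np.ceil((np.max(np.abs(values)) + bin_width / 2) / bin_width))
    edges = bin_width * (np.arange(-m, m + 1) + 0.5)
    edges = np.concatenate([[-(m + 0.5) * bin_width], edges])
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


@dataclass(frozen=True)
class ConductancePoint:
    """Per-well Gd/Gc: mean ± SE over the sampling areas of one well."""

    concentration: float
    gd_gc: float
    se: float
    per_area: tuple[float, ...] = field(default_factory=tuple)
    well_id: str = ""

    @property
    def n_areas(self) -> int:
        return len(self.per_area)


def well_conductance(
    area_fits: list[SlopeFit],
    concentration: float,
    well_id: str = "",
) -> ConductancePoint:
    """Aggregate one well: mean of per-area Gd/Gc with SE across areas.

    The per-well statistic is the mean of per-area estimates (each sampling
    area yields its own regression line), not a pooled regression.
    """
    if not area_fits:
        raise ValueError("no area fits for well")
    vals = np.array([to_conductance(f) for f in area_fits])
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return ConductancePoint(
        concentration, float(np.mean(vals)), se, tuple(vals), well_id
    )
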