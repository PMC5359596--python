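"""Screening-quality statistics: Z/Z' factor, CV_max, EC50 fold-change.

The thresholds follow the NIH/NCATS assay-guidance criteria for plate-based
screens: maximal coefficient of variation below 20 %, EC50 max/min
fold-change below 2, and Z' above 0.4.  Sample (n-1) standard deviations
are used throughout because replicate counts are small (typically 8 rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlateQC",
    "z_factor",
    "cv_max",
    "ec50_fold_change",
    "relative_spread",
    "consistency_report",
    "QC_THRESHOLDS",
]

QC_THRESHOLDS = dict(cv_max_pct=20.0, ec50_fold_change=2.0, z_prime=0.4)


def z_factor(positives, negatives) -> float:
    """Zhang Z-factor: ``1 - 3 (sd_p + sd_n) / |mean_p - mean_n|``.

    Applied to control wells (min- vs max-signal) it is the Z' factor.
    """
    p = np.asarray(positives, dtype=float)
    n = np.asarray(negatives, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("need >= 2 values per group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ValueError("no separation between groups")
    return 1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep


def cv_max(replicate_responses) -> float:
    """Maximal coefficient of variation (percent) across concentrations.

    ``replicate_responses`` is (n_replicates, n_concentrations); the CV at
    each concentration is 100·sd/mean over replicates.  Concentrations with
    zero mean are excluded from the maximum.
    """
    arr = np.asarray(replicate_responses, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 replicates per concentration")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    ok = means != 0
    if not ok.any():
        raise ValueError("all concentrations have zero mean")
    return float(np.max(100.0 * sds[ok] / np.abs(means[ok])))


def ec50_fold_change(ec50s) -> float:
    """max(EC50)/min(EC50) across replicate curves."""
    e = np.asarray(ec50s, dtype=float)
    if e.size < 2:
        raise ValueError("need >= 2 EC50s")
    if np.any(e <= 0):
        raise ValueError("EC50s must be positive")
    return float(e.max() / e.min())


def relative_spread(ec50s) -> float:
    """Alternative spread statistic: max |EC50 - mean| / mean."""
    e = np.asarray(ec50s, dtype=float)
    if e.size < 2:
        raise ValueError("need >= 2 EC50s")
    m = e.mean()
    return float(np.max(np.abs(e - m)) / m)


@dataclass(frozen=True)
class PlateQC:
    """Per-plate screening QC against the NIH criteria."""

    z_prime: float
    cv_max: float  # percent
    ec50_mean: float
    ec50_fold_change: float
    ec50_relative_spread: float
    n_curves: int
    pass_flags: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())

    def summary(self) -> str:
        t = QC_THRESHOLDS
        mark = lambda ok: "PASS" if ok else "FAIL"
        return "\n".join(
            [
                f"Plate QC ({self.n_curves} curves)",
                f"  CV_max          : {self.cv_max:6.2f} %   "
                f"(< {t['cv_max_pct']:.0f} %)  {mark(self.pass_flags['cv_max'])}",
                f"  EC50 mean       : {self.ec50_mean:.4g} M",
                f"  EC50 fold-change: {self.ec50_fold_change:6.3f}     "
                f"(< {t['ec50_fold_change']:.0f})    {mark(self.pass_flags['ec50_fold_change'])}",
                f"  Z'              : {self.z_prime:6.3f}     "
                f"(> {t['z_prime']:.1f})  {mark(self.pass_flags['z_prime'])}",
            ]
        )


@dataclass(frozen=True)
class PlateCurves:
    """Replicate CRCs of one plate on a shared concentration grid.

    ``responses`` is (n_curves, n_concentrations); ``ec50s`` one per curve.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    ec50s: np.ndarray

    def __post_init__(self) -> None:
        if self.responses.ndim != 2:
            raise ValueError("responses must be (n_curves, n_concentrations)")
        if self.responses.shape[1] != len(self.concentrations):
            raise ValueError("responses do not match the concentration grid")
        if self.responses.shape[0] != len(self.ec50s):
            raise ValueError("one EC50 per curve required")


def plate_qc(plate: PlateCurves) -> PlateQC:
    """QC of one plate: CV_max and Z' across replicate curves, EC50 spread.

    Z' contrasts the lowest- and highest-concentration wells of the
    reference agonist (the min- and max-signal controls).
    """
    order = np.argsort(plate.concentrations)
    resp = plate.responses[:, order]
    cv = cv_max(resp)
    fold = ec50_fold_change(plate.ec50s)
    rel = relative_spread(plate.ec50s)
    zp = z_factor(resp[:, -1], resp[:, 0])
    flags = dict(
        cv_max=cv < QC_THRESHOLDS["cv_max_pct"],
        ec50_fold_change=fold < QC_THRESHOLDS["ec50_fold_change"],
        z_prime=zp > QC_THRESHOLDS["z_prime"],
    )
    return PlateQC(
        z_prime=zp,
        cv_max=cv,
        ec50_mean=float(np.mean(plate.ec50s)),
        ec50_fold_change=fold,
        ec50_relative_spread=rel,
        n_curves=plate.responses.shape[0],
        pass_flags=flags,
    )


def consistency_report(plates: list[PlateCurves]) -> dict:
    """Intra-plate QC per plate plus the inter-plate EC50 consistency.

    Returns ``{"plates": [PlateQC, ...], "inter_plate": {...}}`` where the
    inter-plate block holds the mean of plate-mean EC50s and their
    fold-change (max/min) and relative spread across plates.
    """
    if not plates:
        raise ValueError("need >= 1 plate")
    per_plate = [plate_qc(p) for p in plates]
    report = {"plates": per_plate, "inter_plate": None}
    if len(plates) > 1:
        plate_means = np.array([q.ec50_mean for q in per_plate])
        fold = ec50_fold_change(plate_means)
        report["inter_plate"] = dict(
            ec50_mean=float(plate_means.mean()),
            ec50_fold_change=fold,
            ec50_relative_spread=relative_spread(plate_means),
            passed=fold < QC_THRESHOLDS["ec50_fold_change"],
        )
    return report
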