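"""Concentration–response curve fitting: 4-parameter logistic, EC50/IC50.

The response is the per-well conductance ratio Gd/Gc (ascending with an
agonist) or the resistance ratio Rd/Rc (descending, the "inverse sigmoid"),
fitted against log10 concentration with the four-parameter logistic

    f(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill)

Fits are weighted by 1/SE^2 across sampling areas by default.  A response
window smaller than the noise floor yields the flat-curve outcome (the
mock-solution control result) rather than a meaningless EC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .conductance import ConductancePoint

__all__ = [
    "CRCFit",
    "DoseResponseModel",
    "four_param_logistic",
    "fit_crc",
    "minmax_normalize",
    "ic50_from_antagonist_run",
]

HILL_BOUNDS = (0.3, 5.0)


def four_param_logistic(conc, bottom, top, ec50, hill):
    """4PL response at concentration ``conc`` (same units as ``ec50``)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        out = bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)
    out = np.where(c == 0, bottom, out)
    return float(out) if np.ndim(conc) == 0 else out


@dataclass(frozen=True)
class CRCFit:
    """Fitted concentration–response curve.

    ``ec50`` is None for a flat (no-response) curve; ``censored`` marks an
    EC50 outside the tested concentration range (reported, not
    extrapolated-over).  For antagonist runs the ``ec50`` field holds the
    IC50 and ``direction`` is "descending".
    """

    ec50: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    r_squared: float | None
    direction: str  # "ascending" | "descending" | "flat"
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    param_se: dict = field(default_factory=dict)
    censored: bool = False
    inactive: bool = False
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    responses: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def flat(self) -> bool:
        return self.direction == "flat"

    @property
    def ic50(self) -> float | None:
        return self.ec50 if self.direction == "descending" else None

    def predict(self, conc):
        if self.flat:
            raise ValueError("flat curve has no fitted parameters")
        return four_param_logistic(conc, self.bottom, self.top, self.ec50, self.hill)

    def summary(self) -> str:
        if self.flat:
            return (
                "Concentration-response fit\n"
                "  outcome : flat curve, no EC50 (response window below noise floor)"
            )
        label = "IC50" if self.direction == "descending" else "EC50"
        lines = [
            "Concentration-response fit (4-parameter logistic)",
            f"  direction : {self.direction}",
            f"  {label}      : {self.ec50:.4g} M"
            + (" [outside tested range]" if self.censored else ""),
            f"  hill      : {self.hill:.4g}",
            f"  top       : {self.top:.4g}    bottom: {self.bottom:.4g}",
            f"  R-sq      : {self.r_squared:.5f}",
            f"  n points  : {len(self.responses)}",
        ]
        if self.inactive:
            lines.append("  call      : inactive (max inhibition < 50% of window)")
        return "\n".join(lines)


class DoseResponseModel:
    """4PL model of response versus concentration.

    Parameters
    ----------
    concentrations : molar concentrations (> 0 used for fitting).
    responses : per-well mean responses (Gd/Gc or Rd/Rc).
    se : optional per-well standard errors; the fit is weighted by 1/SE^2
        unless ``weighted=False``.
    min_range : response window below which the curve is called flat — the
        control-experiment outcome.  Default 0.2 in conductance-ratio units,
        several times the per-well SE at the simulator's default noise.
    bottom_fixed : optionally pin the bottom asymptote (e.g. 1.0 = control
        conductance).
    """

    def __init__(
        self,
        concentrations,
        responses,
        se=None,
        weighted: bool = True,
        min_range: float = 0.2,
        bottom_fixed: float | None = None,
    ) -> None:
        self.conc = np.asarray(concentrations, dtype=float)
        self.resp = np.asarray(responses, dtype=float)
        if self.conc.shape != self.resp.shape:
            raise ValueError("concentrations and responses must align")
        self.se = None if se is None else np.asarray(se, dtype=float)
        self.weighted = weighted and self.se is not None
        self.min_range = min_range
        self.bottom_fixed = bottom_fixed

    @classmethod
    def from_points(cls, points: list[ConductancePoint], **kw) -> "DoseResponseModel":
        pts = sorted(points, key=lambda p: p.concentration)
        return cls(
            [p.concentration for p in pts],
            [p.gd_gc for p in pts],
            se=[p.se for p in pts],
            **kw,
        )

    @classmethod
    def from_dataframe(
        cls, df, conc_col="concentration", resp_col="gd_gc", se_col=None, **kw
    ) -> "DoseResponseModel":
        se = df[se_col].to_numpy() if se_col else None
        return cls(df[conc_col].to_numpy(), df[resp_col].to_numpy(), se=se, **kw)

    def _noise_floor(self) -> float:
        floor = self.min_range
        if self.se is not None and np.any(self.se > 0):
            floor = max(floor, 3.0 * float(np.median(self.se[self.se > 0])))
        return floor

    def fit(self) -> CRCFit:
        pos = self.conc > 0
        c, y = self.conc[pos], self.resp[pos]
        if len(np.unique(c)) < 4:
            raise ValueError("need >= 4 distinct nonzero concentrations")
        if np.ptp(self.resp) < self._noise_floor():
            return CRCFit(
                None, None, None, None, None, "flat",
                concentrations=self.conc.copy(), responses=self.resp.copy(),
            )
        w = np.ones_like(y)
        if self.weighted:
            se = self.se[pos]
            # guard degenerate zero-SE wells with the median SE
            se = np.where(se > 0, se, np.median(se[se > 0]) if np.any(se > 0) else 1.0)
            w = 1.0 / se
        logc = np.log10(c)
        ascending = y[np.argmax(logc)] >= y[np.argmin(logc)]

        lo_b = -np.inf if self.bottom_fixed is None else self.bottom_fixed
        # parameters: bottom, top, log10 ec50, hill
        p0 = np.array(
            [
                float(np.min(y)) if ascending else float(np.max(y)),
                float(np.max(y)) if ascending else float(np.min(y)),
                float(np.median(logc)),
                1.0,
            ]
        )
        lower = [-np.inf, -np.inf, logc.min() - 3, HILL_BOUNDS[0]]
        upper = [np.inf, np.inf, logc.max() + 3, HILL_BOUNDS[1]]
        if self.bottom_fixed is not None:
            p0[0] = self.bottom_fixed
            lower[0] = self.bottom_fixed - 1e-12
            upper[0] = self.bottom_fixed + 1e-12

        def resid(p):
            return w * (four_param_logistic(c, p[0], p[1], 10.0 ** p[2], p[3]) - y)

        sol = least_squares(
            resid, p0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        if not sol.success:
            raise RuntimeError(f"CRC fit did not converge: {sol.message}")
        bottom, top, log_ec50, hill = sol.x
        ec50 = 10.0**log_ec50
        fitted = four_param_logistic(c, bottom, top, ec50, hill)
        residuals = y - fitted
        ss_res = float(residuals @ residuals)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r_sq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        # parameter SEs from the weighted Jacobian
        se_map = {}
        try:
            jtj = sol.jac.T @ sol.jac
            dof = max(len(y) - len(sol.x), 1)
            cov = np.linalg.pinv(jtj) * 2 * sol.cost / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            se_map = dict(
                bottom=se[0], top=se[1],
                ec50=se[2] * ec50 * np.log(10), hill=se[3],
            )
        except np.linalg.LinAlgError:
            pass

        return CRCFit(
            ec50=float(ec50),
            hill=float(hill),
            top=float(top),
            bottom=float(bottom),
            r_squared=float(r_sq),
            direction="ascending" if top >= bottom else "descending",
            residuals=residuals,
            param_se=se_map,
            censored=not (c.min() <= ec50 <= c.max()),
            concentrations=self.conc.copy(),
            responses=self.resp.copy(),
        )


def fit_crc(points, **kw) -> CRCFit:
    """Fit a 4PL CRC to per-well conductance points (weighted by 1/SE^2)."""
    if points and isinstance(points[0], ConductancePoint):
        return DoseResponseModel.from_points(list(points), **kw).fit()
    conc, resp = zip(*points)
    return DoseResponseModel(conc, resp, **kw).fit()


def minmax_normalize(values) -> np.ndarray:
    """Map fitted-curve values affinely onto [0, 1] for cross-plate overlay.

    Applied to fitted curves only, never before fitting.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise ValueError("degenerate normalization: constant input")
    return (v - lo) / (hi - lo)


def ic50_from_antagonist_run(
    antagonist_concentrations,
    responses,
    agonist_alone_response: float,
    control_response: float = 1.0,
    se=None,
    **kw,
) -> CRCFit:
    """Descending 4PL of Gd/Gc versus antagonist concentration.

    The agonist is co-applied at a fixed concentration; ``agonist_alone_response``
    (the anchor wells with no antagonist) and ``control_response`` (no drug
    at all) define the response window.  If the maximal inhibition reaches
    less than 50 % of that window the compound is called inactive and no
    IC50 is reported.  An IC50 outside the tested range is flagged censored.
    """
    if agonist_alone_response is None:
        raise ValueError("missing agonist-alone anchor wells")
    conc = np.asarray(antagonist_concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    window = agonist_alone_response - control_response
    if window <= 0:
        raise ValueError("agonist-alone response does not exceed control")
    inhibition = agonist_alone_response - np.min(resp)
    if inhibition < 0.5 * window:
        return CRCFit(
            None, None, None, None, None, "flat",
            inactive=True, concentrations=conc, responses=resp,
        )
    fit = DoseResponseModel(conc, resp, se=se, **kw).fit()
    if fit.flat:
        return CRCFit(
            None, None, None, None, None, "flat",
            inactive=True, concentrations=conc, responses=resp,
        )
    if fit.direction != "descending":
        raise RuntimeError("antagonist run fitted ascending; check inputs")
    return fit
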