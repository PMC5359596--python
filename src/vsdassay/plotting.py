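"""Semilogarithmic CRC plots and scatter diagnostics (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .conductance import PixelPairSet, SlopeFit
from .dose_response import CRCFit, minmax_normalize


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(4.5, 3.5))
    return ax


def plot_crc(fit: CRCFit, ax=None, normalized: bool = False, label: str | None = None):
    """Mean ± SE points with the fitted sigmoid on a log concentration axis."""
    ax = _axes(ax)
    conc = np.asarray(fit.concentrations, float)
    resp = np.asarray(fit.responses, float)
    pos = conc > 0
    if fit.flat:
        ax.semilogx(conc[pos], resp[pos], "o", label=label or "flat (no EC50)")
    else:
        grid = np.logspace(
            np.log10(conc[pos].min()) - 0.5, np.log10(conc[pos].max()) + 0.5, 200
        )
        curve = fit.predict(grid)
        pts = resp[pos]
        if normalized:
            lo, hi = curve.min(), curve.max()
            curve = minmax_normalize(curve)
            pts = (pts - lo) / (hi - lo)
        ax.semilogx(conc[pos], pts, "o")
        ax.semilogx(grid, curve, "-", label=label or f"EC50 = {fit.ec50:.3g} M")
    ax.set_xlabel("concentration (M)")
    ax.set_ylabel("normalized response" if normalized else "Gd/Gc")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pair_scatter(pairs: PixelPairSet, fit: SlopeFit | None = None, ax=None):
    """Per-pixel reference-vs-test dF/F scatter with the regression line(s)."""
    ax = _axes(ax)
    ax.plot(pairs.x, pairs.y, ".", ms=2, alpha=0.4)
    if fit is not None:
        xx = np.linspace(pairs.x.min(), pairs.x.max(), 2)
        ax.plot(xx, fit.slope_all * xx, "r-", lw=1.5,
                label=f"Rd/Rc = {fit.slope_all:.3f}")
        if fit.slope_neg is not None:
            xn = np.linspace(pairs.x.min(), 0, 2)
            ax.plot(xn, fit.slope_neg * xn, "g--", lw=1)
        if fit.slope_pos is not None:
            xp = np.linspace(0, pairs.x.max(), 2)
            ax.plot(xp, fit.slope_pos * xp, "b--", lw=1)
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(r"reference $\Delta F_c/F_{Rc}$")
    ax.set_ylabel(r"test $\Delta F_d/F_{Rd}$")
    return ax
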