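"""Passive-membrane forward model for electric-field stimulation.

A cell in a uniform extracellular field driven by a constant-current pulse
polarizes along the field axis: the membrane facing the cathode depolarizes
and the membrane facing the anode hyperpolarizes, with a cos(theta) profile
in the angle theta between the outward membrane normal and the field
direction.  At the current plateau the local potential change obeys Ohm's
law, so it scales with the effective local membrane resistance.  Drugs that
open ligand-gated channels raise membrane conductance by a Hill-shaped fold
``g`` and therefore shrink the induced potential change by ``1/g``.

The model is deliberately lumped (no cable equation, no Schwan theory):
local dV = k * I * R * cos(theta) with first-order RC charging.  The
downstream analysis only assumes Ohm's law at plateau, which this model
reproduces exactly, making it a closed-form oracle for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellModel",
    "PulseProtocol",
    "FieldGeometry",
    "DrugModel",
    "DRIVE_GAIN_MV",
    "drug_conductance_fold",
    "antagonist_inhibition",
    "local_conductance_fold",
    "induced_delta_v",
    "induced_delta_v_profile",
    "whole_cell_mean_dv",
]

#: Calibration constant of the simulator: plateau |dV| in mV produced on the
#: field axis by one unit of pulse amplitude on a control cell (r_rel = 1).
#: With the default dye sensitivity (-0.0015 / mV) this puts the control
#: plateau |dF/F| at ~5 %, the regime of a bright fast-dye recording.
DRIVE_GAIN_MV: float = 33.0


@dataclass(frozen=True)
class CellModel:
    """Geometry and passive electrical properties of one simulated cell.

    Parameters
    ----------
    center : (row, col) position in pixels.
    radius : outer radius of the membrane annulus, pixels.
    tau_m : membrane time constant, ms.
    r_rel : baseline membrane resistance relative to the control cell (1.0).
    f_rest : resting membrane fluorescence, camera counts.
    dye_sens : fractional fluorescence change per mV of depolarization;
        negative for di-4-ANEPPS-like fast dyes (depolarization dims).
    ring_width : thickness of the fluorescent membrane annulus, pixels.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 20.0
    tau_m: float = 3.0
    r_rel: float = 1.0
    f_rest: float = 40000.0
    dye_sens: float = -0.0015
    ring_width: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.r_rel <= 0:
            raise ValueError("r_rel must be > 0")
        if self.f_rest <= 0:
            raise ValueError("f_rest must be > 0")
        if not 0 < self.ring_width <= self.radius:
            raise ValueError("ring_width must be in (0, radius]")


@dataclass(frozen=True)
class PulseProtocol:
    """Constant-current test pulse.

    The pulse is long relative to the membrane time constant so that the
    plateau is fully established at ``plateau_sample_time`` (the default is
    25 tau for the default cell).  ``amplitude`` is the current drive in
    arbitrary units; only ratios of responses are meaningful, so no absolute
    current calibration is needed.
    """

    shape: str = "biphasic-symmetric"
    phase_duration: float = 80.0
    amplitude: float = 1.0
    plateau_sample_time: float = 75.0
    inter_pulse_interval: float = 100.0

    def __post_init__(self) -> None:
        if self.shape not in ("monophasic", "biphasic-symmetric"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be > 0")
        if not 0 <= self.plateau_sample_time <= self.phase_duration:
            raise ValueError("plateau_sample_time must lie within the phase")

    @property
    def total_duration(self) -> float:
        n = 2 if self.shape == "biphasic-symmetric" else 1
        return n * self.phase_duration


@dataclass(frozen=True)
class FieldGeometry:
    """Uniform field in the image plane, pointing from anode to cathode.

    ``direction`` is a unit vector in (row, col) image coordinates.
    """

    direction: tuple[float, float] = (0.0, 1.0)
    uniform: bool = True

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("field direction must be a unit vector")
        if not self.uniform:
            raise ValueError("only uniform fields are supported")


@dataclass(frozen=True)
class DrugModel:
    """Hill-form conductance model of a channel-modulating compound.

    ``g_max_fold`` is the whole-membrane conductance fold at saturation
    (>1 for agonist-opened channels).  ``rectification`` is the ratio of the
    drug-added conductance on the hyperpolarized membrane side to that on
    the depolarized side: 1 = ohmic channel, <1 = outward rectification
    (drug effect weaker under hyperpolarization).
    """

    ec50: float = 1e-6
    hill: float = 1.0
    g_max_fold: float = 5.0
    rectification: float = 1.0
    name: str = "agonist"

    def __post_init__(self) -> None:
        for attr in ("ec50", "hill", "g_max_fold", "rectification"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")


def drug_conductance_fold(conc, drug: DrugModel):
    """Whole-membrane conductance fold at agonist concentration ``conc`` (M).

    Hill relation ``1 + (g_max_fold - 1) * c^h / (c^h + ec50^h)``; returns
    1.0 at zero concentration and ``g_max_fold`` at saturation.  Accepts a
    scalar or array concentration.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    ch = np.power(c, drug.hill)
    fold = 1.0 + (drug.g_max_fold - 1.0) * ch / (ch + drug.ec50**drug.hill)
    return float(fold) if np.ndim(conc) == 0 else fold


def antagonist_inhibition(conc, antagonist: DrugModel):
    """Fractional block of the agonist-added conductance by an antagonist.

    Returns ``1 / (1 + (c / ic50)^h)`` — 1 at zero antagonist, 0 at
    saturation.  ``antagonist.ec50`` plays the role of the IC50.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    frac = 1.0 / (1.0 + np.power(c / antagonist.ec50, antagonist.hill))
    return float(frac) if np.ndim(conc) == 0 else frac


def local_conductance_fold(cos_theta, g_fold: float, rectification: float = 1.0):
    """Hemisphere-resolved conductance fold.

    The drug-added conductance ``g_fold - 1`` applies fully on the
    depolarized hemisphere (cos(theta) >= 0, facing the cathode) and scaled
    by ``rectification`` on the hyperpolarized hemisphere, which reproduces
    the unequal scatter-plot slopes of an outward-rectifying channel without
    channel-level kinetics.
    """
    if g_fold <= 0:
        raise ValueError("g_fold must be > 0")
    g_hyp = 1.0 + (g_fold - 1.0) * rectification
    return np.where(np.asarray(cos_theta) >= 0, g_fold, g_hyp)


def _phase_sign_and_time(pulse: PulseProtocol, t: float) -> tuple[float, float]:
    if t < 0:
        raise ValueError("t must be >= 0")
    if t <= pulse.phase_duration:
        return 1.0, t
    if pulse.shape == "biphasic-symmetric" and t <= 2 * pulse.phase_duration:
        # second phase: opposite polarity, charging restarted (the inter-phase
        # residual is negligible for pulses many tau long)
        return -1.0, t - pulse.phase_duration
    raise ValueError("t beyond pulse duration")


def induced_delta_v_profile(
    cell: CellModel,
    pulse: PulseProtocol,
    cos_theta,
    g_fold=1.0,
    t: float | None = None,
    drive_gain_mv: float = DRIVE_GAIN_MV,
):
    """Vectorized induced potential change (mV) for membrane elements.

    ``cos_theta`` is the cosine of the angle between each element's outward
    normal and the field direction; ``g_fold`` may be an array of local
    conductance folds (rectification).  The charging time constant scales as
    ``tau_m / g_fold`` (passive RC membrane: more conductance charges
    faster), and the plateau amplitude as ``r_rel / g_fold`` (Ohm's law at
    constant current).
    """
    if t is None:
        t = pulse.plateau_sample_time
    sign, tp = _phase_sign_and_time(pulse, t)
    g = np.asarray(g_fold, dtype=float)
    if np.any(g <= 0):
        raise ValueError("g_fold must be > 0")
    charging = 1.0 - np.exp(-tp * g / cell.tau_m)
    return (
        sign
        * drive_gain_mv
        * pulse.amplitude
        * (cell.r_rel / g)
        * np.asarray(cos_theta, dtype=float)
        * charging
    )


def induced_delta_v(
    cell: CellModel,
    field: FieldGeometry,
    pulse: PulseProtocol,
    membrane_angle: float,
    g_fold: float = 1.0,
    t: float | None = None,
    drive_gain_mv: float = DRIVE_GAIN_MV,
) -> float:
    """Induced potential change (mV) at one membrane point.

    ``membrane_angle`` is the angle (radians) between the outward membrane
    normal and the field direction; the ``field`` argument fixes the
    convention (normals are measured against ``field.direction``).
    """
    del field  # direction already folded into membrane_angle
    out = induced_delta_v_profile(
        cell, pulse, math.cos(membrane_angle), g_fold, t, drive_gain_mv
    )
    return float(out)


def whole_cell_mean_dv(
    cell: CellModel,
    field: FieldGeometry,
    pulse: PulseProtocol,
    t: float | None = None,
    g_fold: float = 1.0,
    n_angles: int = 720,
    drive_gain_mv: float = DRIVE_GAIN_MV,
) -> float:
    """Membrane-averaged induced potential change (mV).

    Samples the membrane uniformly in angle; for a centrally symmetric cell
    the depolarized and hyperpolarized halves cancel and the mean is zero to
    numerical precision — the whole-cell fluorescence null seen when a
    symmetric cell is stimulated.
    """
    angles = 2.0 * np.pi * (np.arange(n_angles) + 0.5) / n_angles
    dv = induced_delta_v_profile(
        cell, pulse, np.cos(angles), g_fold, t, drive_gain_mv
    )
    return float(np.mean(dv))
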