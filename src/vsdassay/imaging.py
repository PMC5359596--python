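"""Synthetic-plate renderer: the two-passage, two-frames-per-passage protocol.

One "sampling area" is a field of view containing several dye-loaded cells
drawn as membrane annuli (the dye is membrane-localized) over a dim
interior.  A passage acquires two frames — one before the pulse (resting
fluorescence F_R) and one during the current plateau (F_S).  The protocol
compares a reference passage (no compound) with a test passage acquired
after adding a mock solution or a drug dilution; between passages the stage
repositions (small integer shift) and the dye bleaches slightly.

With noise disabled every frame is an exact closed-form function of the
configuration, so the renderer doubles as the oracle for the analysis
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .biophysics import (
    DRIVE_GAIN_MV,
    CellModel,
    DrugModel,
    FieldGeometry,
    PulseProtocol,
    antagonist_inhibition,
    drug_conductance_fold,
    local_conductance_fold,
    induced_delta_v_profile,
)

__all__ = [
    "CameraModel",
    "WellSpec",
    "PlateMap",
    "PassageRecord",
    "AreaSimulation",
    "SceneParams",
    "render_frame",
    "scene_delta_v_map",
    "simulate_area",
    "simulate_passage_pair",
]


@dataclass(frozen=True)
class CameraModel:
    """Generic EM-CCD-like camera: shot noise plus Gaussian read noise."""

    read_noise_sd: float = 6.0
    shot_noise: bool = True
    bit_depth: int = 16
    binning_native: int = 1

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")
        if self.binning_native < 1:
            raise ValueError("binning_native must be >= 1")

    @property
    def full_well(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class WellSpec:
    row: int
    col: int
    drug: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def well_id(self) -> str:
        return f"{chr(ord('A') + self.row)}{self.col + 1:02d}"


@dataclass(frozen=True)
class PlateMap:
    """Wells to image, each with a drug id and concentration (M)."""

    wells: tuple[WellSpec, ...]
    sampling_areas_per_well: int = 5
    cells_per_area: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.wells) == 0:
            raise ValueError("plate map has no wells")
        if not 1 <= self.sampling_areas_per_well <= 9:
            raise ValueError("sampling_areas_per_well must be in 1..9")
        if self.cells_per_area < 1:
            raise ValueError("cells_per_area must be >= 1")

    @classmethod
    def single_row(
        cls,
        concentrations,
        drug: str = "agonist",
        row: int = 0,
        sampling_areas_per_well: int = 5,
        cells_per_area: int = 6,
        seed: int = 0,
    ) -> "PlateMap":
        """One plate row (up to 8 wells), one concentration per well."""
        wells = tuple(
            WellSpec(row, j, drug, float(c)) for j, c in enumerate(concentrations)
        )
        return cls(wells, sampling_areas_per_well, cells_per_area, seed)


@dataclass(frozen=True)
class PassageRecord:
    """The two frames of one sampling area in one passage."""

    f_pre: np.ndarray
    f_plateau: np.ndarray
    passage: str  # "reference" | "test"
    well_id: str = ""
    area_id: int = 0

    def __post_init__(self) -> None:
        if self.f_pre.shape != self.f_plateau.shape:
            raise ValueError("passage frames must have the same shape")
        if self.passage not in ("reference", "test"):
            raise ValueError("passage must be 'reference' or 'test'")


@dataclass(frozen=True)
class AreaSimulation:
    """Reference/test passage pair of one sampling area plus ground truth."""

    reference: PassageRecord
    test: PassageRecord
    well_id: str
    area_id: int
    drug: str
    concentration: float
    truth: dict


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters shared by every area of a run."""

    frame_shape: tuple[int, int] = (192, 192)
    background: float = 200.0
    interior_fraction: float = 0.25
    drive_gain_mv: float = DRIVE_GAIN_MV
    bleach_fraction: float = 0.02
    shift_max: int = 3
    cell_radius_range: tuple[float, float] = (16.0, 22.0)
    f_rest_jitter: float = 0.15
    noise: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.bleach_fraction < 0.5:
            raise ValueError("bleach_fraction must be in [0, 0.5)")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")


def _cell_pixels(cell: CellModel, shape: tuple[int, int]):
    """Membrane-ring and interior pixel indices plus outward-normal vectors."""
    r0, c0 = cell.center
    rad = cell.radius
    rlo = max(int(np.floor(r0 - rad)) - 1, 0)
    rhi = min(int(np.ceil(r0 + rad)) + 2, shape[0])
    clo = max(int(np.floor(c0 - rad)) - 1, 0)
    chi = min(int(np.ceil(c0 + rad)) + 2, shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    dist = np.hypot(dr, dc)
    mem = (dist > rad - cell.ring_width) & (dist <= rad)
    interior = dist <= rad - cell.ring_width
    with np.errstate(invalid="ignore", divide="ignore"):
        nr = np.where(dist > 0, dr / dist, 0.0)
        nc = np.where(dist > 0, dc / dist, 0.0)
    return (
        (rr[mem], cc[mem], nr[mem], nc[mem]),
        (rr[interior], cc[interior]),
    )


def scene_delta_v_map(
    cells: list[CellModel],
    field: FieldGeometry,
    pulse: PulseProtocol,
    frame_shape: tuple[int, int],
    g_fold: float = 1.0,
    rectification: float = 1.0,
    t: float | None = None,
    drive_gain_mv: float = DRIVE_GAIN_MV,
) -> np.ndarray:
    """Per-pixel induced-potential map (mV), nonzero on membrane rings only."""
    dv = np.zeros(frame_shape, dtype=float)
    fr, fc = field.direction
    for cell in cells:
        (mr, mc, nr, nc), _ = _cell_pixels(cell, frame_shape)
        cos_theta = nr * fr + nc * fc
        g_loc = local_conductance_fold(cos_theta, g_fold, rectification)
        dv[mr, mc] = induced_delta_v_profile(
            cell, pulse, cos_theta, g_loc, t, drive_gain_mv
        )
    return dv


def _scene_expectation(
    cells: list[CellModel],
    dv_field: np.ndarray | None,
    frame_shape: tuple[int, int],
    background: float,
    interior_fraction: float,
) -> np.ndarray:
    exp = np.full(frame_shape, float(background))
    occupancy = np.zeros(frame_shape, dtype=np.uint8)
    for cell in cells:
        (mr, mc, *_), (ir, ic) = _cell_pixels(cell, frame_shape)
        exp[ir, ic] += interior_fraction * cell.f_rest
        factor = 1.0
        if dv_field is not None:
            factor = 1.0 + cell.dye_sens * dv_field[mr, mc]
        exp[mr, mc] += cell.f_rest * factor
        occupancy[mr, mc] += 1
    if np.any(occupancy > 1):
        warnings.warn("overlapping cells: fluorescence summed", stacklevel=2)
    return exp


def render_frame(
    cells: list[CellModel],
    dv_field: np.ndarray | None,
    camera: CameraModel,
    rng: np.random.Generator | int | None = None,
    frame_shape: tuple[int, int] = (192, 192),
    background: float = 200.0,
    interior_fraction: float = 0.25,
    gain: float = 1.0,
) -> np.ndarray:
    """Render one frame.

    ``dv_field`` is a full-frame map of induced potential (mV); membrane-ring
    pixels respond linearly through each cell's dye sensitivity.  ``gain`` is
    a global multiplicative factor applied to the expectation (used for
    bleaching).  With ``rng=None`` the noiseless expectation is returned and
    the render is an exact closed form; otherwise shot noise (Poisson on the
    expected counts) and Gaussian read noise are applied and the result is
    clipped to the camera's dynamic range.
    """
    for cell in cells:
        r0, c0 = cell.center
        if not (
            cell.radius <= r0 <= frame_shape[0] - cell.radius
            and cell.radius <= c0 <= frame_shape[1] - cell.radius
        ):
            raise ValueError("cell does not fit inside the frame")
    exp = gain * _scene_expectation(
        cells, dv_field, frame_shape, background, interior_fraction
    )
    if rng is None:
        return exp
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img = rng.poisson(exp).astype(float) if camera.shot_noise else exp.copy()
    if camera.read_noise_sd > 0:
        img += rng.normal(0.0, camera.read_noise_sd, size=exp.shape)
    return np.clip(img, 0.0, camera.full_well)


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    scene: SceneParams,
) -> list[CellModel]:
    """Random non-overlapping cells with margin for shifts and registration."""
    rlo, rhi = scene.cell_radius_range
    margin = rhi + scene.shift_max + 4
    base = CellModel()
    cells: list[CellModel] = []
    for _ in range(n_cells):
        for _attempt in range(200):
            r = rng.uniform(margin, scene.frame_shape[0] - margin)
            c = rng.uniform(margin, scene.frame_shape[1] - margin)
            rad = rng.uniform(rlo, rhi)
            ok = all(
                np.hypot(r - o.center[0], c - o.center[1]) > rad + o.radius + 2
                for o in cells
            )
            if ok:
                break
        f_rest = base.f_rest * (1.0 + scene.f_rest_jitter * rng.uniform(-1, 1))
        cells.append(
            replace(base, center=(float(r), float(c)), radius=float(rad), f_rest=f_rest)
        )
    return cells


def simulate_area(
    cells: list[CellModel],
    field: FieldGeometry,
    pulse: PulseProtocol,
    camera: CameraModel,
    scene: SceneParams,
    g_fold: float,
    rectification: float = 1.0,
    shift: tuple[int, int] = (0, 0),
    rng: np.random.Generator | None = None,
    well_id: str = "",
    area_id: int = 0,
    resting_dv_shift_mv: float = 0.0,
) -> tuple[PassageRecord, PassageRecord]:
    """Render the four frames of one sampling area.

    Reference passage at control conductance; test passage with the drug
    conductance fold ``g_fold``, shifted rigidly by ``shift`` (stage
    repositioning), bleached by ``scene.bleach_fraction``, and optionally
    with a uniform resting-potential drift ``resting_dv_shift_mv`` (affects
    both test frames equally; the ratiometric analysis is insensitive to it).
    """
    kw = dict(
        camera=camera,
        frame_shape=scene.frame_shape,
        background=scene.background,
        interior_fraction=scene.interior_fraction,
    )
    noise_rng = rng if scene.noise else None

    def frame(cl, dv, gain):
        return render_frame(cl, dv, rng=noise_rng, gain=gain, **kw)

    dv_ref = scene_delta_v_map(
        cells, field, pulse, scene.frame_shape, 1.0, 1.0,
        drive_gain_mv=scene.drive_gain_mv,
    )
    ref = PassageRecord(
        frame(cells, None, 1.0),
        frame(cells, dv_ref, 1.0),
        "reference",
        well_id,
        area_id,
    )

    shifted = [
        replace(c, center=(c.center[0] + shift[0], c.center[1] + shift[1]))
        for c in cells
    ]
    dv_test = scene_delta_v_map(
        shifted, field, pulse, scene.frame_shape, g_fold, rectification,
        drive_gain_mv=scene.drive_gain_mv,
    )
    rest = None
    if resting_dv_shift_mv != 0.0:
        rest = np.zeros(scene.frame_shape)
        for c in shifted:
            (mr, mc, *_), _ = _cell_pixels(c, scene.frame_shape)
            rest[mr, mc] = resting_dv_shift_mv
        dv_test = dv_test + rest
    gain = 1.0 - scene.bleach_fraction
    test = PassageRecord(
        frame(shifted, rest, gain),
        frame(shifted, dv_test, gain),
        "test",
        well_id,
        area_id,
    )
    return ref, test


def simulate_passage_pair(
    platemap: PlateMap,
    drug: DrugModel,
    pulse: PulseProtocol | None = None,
    field: FieldGeometry | None = None,
    camera: CameraModel | None = None,
    scene: SceneParams | None = None,
    antagonist: DrugModel | None = None,
    agonist_conc: float = 0.0,
) -> list[AreaSimulation]:
    """Simulate every (well, area) of a plate map.

    For an agonist run each well's concentration drives
    :func:`drug_conductance_fold` directly.  For an antagonist run
    (``antagonist`` given), wells titrate the antagonist while the agonist is
    co-applied at the fixed ``agonist_conc``; the drug-added conductance is
    scaled by the antagonist's fractional block.

    One RNG stream per (well, area), spawned from the plate seed, so results
    are independent of execution order.
    """
    pulse = pulse or PulseProtocol()
    field = field or FieldGeometry()
    camera = camera or CameraModel()
    scene = scene or SceneParams()
    out: list[AreaSimulation] = []
    for w_idx, well in enumerate(platemap.wells):
        if antagonist is None:
            g_fold = drug_conductance_fold(well.concentration, drug)
        else:
            g_ag = drug_conductance_fold(agonist_conc, drug)
            block = antagonist_inhibition(well.concentration, antagonist)
            g_fold = 1.0 + (g_ag - 1.0) * block
        for area in range(platemap.sampling_areas_per_well):
            rng = np.random.default_rng(
                np.random.SeedSequence([platemap.seed, w_idx, area])
            )
            cells = _place_cells(rng, platemap.cells_per_area, scene)
            if scene.shift_max > 0:
                shift = tuple(
                    int(s)
                    for s in rng.integers(-scene.shift_max, scene.shift_max + 1, 2)
                )
            else:
                shift = (0, 0)
            ref, test = simulate_area(
                cells, field, pulse, camera, scene,
                g_fold=float(g_fold),
                rectification=drug.rectification,
                shift=shift,
                rng=rng,
                well_id=well.well_id,
                area_id=area,
            )
            truth = {
                "g_fold": float(g_fold),
                "shift": list(shift),
                "ec50": drug.ec50,
                "hill": drug.hill,
                "g_max_fold": drug.g_max_fold,
                "rectification": drug.rectification,
                "concentration": well.concentration,
            }
            if antagonist is not None:
                truth.update(
                    ic50=antagonist.ec50,
                    antagonist_hill=antagonist.hill,
                    agonist_conc=agonist_conc,
                )
            out.append(
                AreaSimulation(
                    ref, test, well.well_id, area, well.drug,
                    well.concentration, truth,
                )
            )
    return out
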