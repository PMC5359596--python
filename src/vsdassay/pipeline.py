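"""End-to-end orchestration: config, simulate -> analyze -> CRC -> QC -> score.

The run configuration is a plain schema-versioned mapping (YAML/JSON on
disk); all defaults are written back into the output bundle so a run is
self-describing.  Analysis failures are isolated per sampling area: a bad
area is skipped with a logged reason and the plate result is built from the
remaining areas.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .biophysics import DrugModel, FieldGeometry, PulseProtocol
from .conductance import (
    ConductancePoint,
    SlopeFit,
    fit_slope,
    pair_pixels,
    rectification_index,
    well_conductance,
)
from .dose_response import CRCFit, fit_crc
from .image_analysis import (
    AnalysisError,
    bin_image,
    build_shape_mask,
    compute_dff,
    register,
    translate,
)
from .imaging import (
    AreaSimulation,
    CameraModel,
    PassageRecord,
    PlateMap,
    SceneParams,
    WellSpec,
    simulate_passage_pair,
)
from .qc_metrics import PlateCurves, consistency_report

log = logging.getLogger("vsdassay")

SCHEMA_VERSION = 1

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "AreaResult",
    "ResultBundle",
    "analyze_area",
    "analyze_simulations",
    "simulate_to_dir",
    "analyze_dir",
    "load_area_stack",
    "score_bundle",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the image-analysis and regression stages."""

    binning: int = 4
    object_threshold: float = 0.2
    ring_depth: int = 3
    smooth_size: int = 3
    min_component: int = 8
    min_mask_pixels: int = 50
    max_shift: int = 5
    f_floor: float = 50.0
    plausibility: float = 0.5
    x_deadband: float = 0.002
    min_pairs: int = 50
    robust: bool = False
    free_intercept: bool = False
    weighted_crc: bool = True
    crc_min_range: float = 0.2
    crc_bottom_fixed: float | None = None


@dataclass(frozen=True)
class RunConfig:
    """Full, schema-versioned description of a simulate+analyze run."""

    platemap: PlateMap
    drug: DrugModel
    pulse: PulseProtocol = field(default_factory=PulseProtocol)
    fieldgeom: FieldGeometry = field(default_factory=FieldGeometry)
    camera: CameraModel = field(default_factory=CameraModel)
    scene: SceneParams = field(default_factory=SceneParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    antagonist: DrugModel | None = None
    agonist_conc: float = 0.0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = asdict(self)
        d["platemap"]["wells"] = [asdict(w) for w in self.platemap.wells]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config field 'schema_version' must be {SCHEMA_VERSION}, got {version!r}"
            )
        def sub(key, typ, required=False):
            if key not in d or d[key] is None:
                if required:
                    raise ValueError(f"config is missing required field '{key}'")
                d.pop(key, None)
                return None
            val = d.pop(key)
            try:
                return typ(**val) if isinstance(val, dict) else val
            except TypeError as exc:
                raise ValueError(f"invalid config field '{key}': {exc}") from exc

        pm = d.pop("platemap", None)
        if pm is None:
            raise ValueError("config is missing required field 'platemap'")
        if "seed" not in pm:
            raise ValueError("config is missing required field 'platemap.seed'")
        wells = tuple(WellSpec(**w) for w in pm.pop("wells"))
        platemap = PlateMap(wells=wells, **pm)
        fg = d.pop("fieldgeom", None)
        if fg is not None and isinstance(fg, dict):
            fg["direction"] = tuple(fg["direction"])
            fg = FieldGeometry(**fg)
        scene = d.pop("scene", None)
        if scene is not None and isinstance(scene, dict):
            for k in ("frame_shape", "cell_radius_range"):
                if k in scene:
                    scene[k] = tuple(scene[k])
            scene = SceneParams(**scene)
        cfg = cls(
            platemap=platemap,
            drug=sub("drug", DrugModel, required=True),
            pulse=sub("pulse", PulseProtocol) or PulseProtocol(),
            fieldgeom=fg or FieldGeometry(),
            camera=sub("camera", CameraModel) or CameraModel(),
            scene=scene or SceneParams(),
            analysis=sub("analysis", AnalysisParams) or AnalysisParams(),
            antagonist=sub("antagonist", DrugModel),
            agonist_conc=float(d.pop("agonist_conc", 0.0)),
        )
        if d:
            raise ValueError(f"unknown config fields: {sorted(d)}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, platemap=replace(self.platemap, seed=int(seed)))


@dataclass(frozen=True)
class AreaResult:
    """Per-area analysis output."""

    well_id: str
    area_id: int
    concentration: float
    shift: tuple[int, int]
    slope: SlopeFit
    gd_gc: float

    @property
    def rectification(self) -> float | None:
        return rectification_index(self.slope)


@dataclass
class ResultBundle:
    """Everything one analyze run produces, traceable to its inputs."""

    area_table: pd.DataFrame
    well_table: pd.DataFrame
    crc: CRCFit | None
    qc: dict | None
    failures: list[dict]
    provenance: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.area_table.to_csv(outdir / "areas.csv", index=False)
        self.well_table.to_csv(outdir / "wells.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "failures": self.failures,
            "crc": _crc_to_dict(self.crc),
            "qc": self.qc,
        }
        (outdir / "results.json").write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def _crc_to_dict(crc: CRCFit | None) -> dict | None:
    if crc is None:
        return None
    return dict(
        ec50=crc.ec50,
        hill=crc.hill,
        top=crc.top,
        bottom=crc.bottom,
        r_squared=crc.r_squared,
        direction=crc.direction,
        censored=crc.censored,
        inactive=crc.inactive,
        concentrations=list(map(float, crc.concentrations)),
        responses=list(map(float, crc.responses)),
    )


def analyze_area(
    ref: PassageRecord, test: PassageRecord, params: AnalysisParams
) -> AreaResult:
    """register -> bin -> mask -> dF/F -> pair -> slope -> conductance."""
    t0 = time.perf_counter()
    shift = register(ref.f_pre, test.f_pre, params.max_shift)
    test_pre = translate(test.f_pre, (-shift[0], -shift[1]))
    test_plat = translate(test.f_plateau, (-shift[0], -shift[1]))

    b = params.binning
    ref_pre = bin_image(ref.f_pre, b)
    ref_plat = bin_image(ref.f_plateau, b)
    test_pre = bin_image(test_pre, b)
    test_plat = bin_image(test_plat, b)

    mask = build_shape_mask(
        ref_pre,
        object_threshold=params.object_threshold,
        ring_depth=params.ring_depth,
        smooth_size=params.smooth_size,
        min_component=params.min_component,
        min_mask_pixels=params.min_mask_pixels,
    )
    dff_kw = dict(f_floor=params.f_floor, plausibility=params.plausibility)
    dff_ref = compute_dff(ref_pre, ref_plat, mask, passage="reference", **dff_kw)
    dff_test = compute_dff(test_pre, test_plat, mask, passage="test", **dff_kw)
    pairs = pair_pixels(dff_ref, dff_test)
    fit = fit_slope(
        pairs,
        x_deadband=params.x_deadband,
        min_pairs=params.min_pairs,
        robust=params.robust,
        free_intercept=params.free_intercept,
    )
    log.debug(
        "area %s/%d: shift=%s n=%d slope=%.4f (%.1f ms)",
        ref.well_id, ref.area_id, shift, fit.n_pairs, fit.slope_all,
        1e3 * (time.perf_counter() - t0),
    )
    return AreaResult(
        well_id=ref.well_id,
        area_id=ref.area_id,
        concentration=np.nan,
        shift=shift,
        slope=fit,
        gd_gc=fit.gd_gc,
    )


def analyze_simulations(
    sims: list[AreaSimulation],
    params: AnalysisParams | None = None,
    provenance: dict | None = None,
) -> ResultBundle:
    """Analyze a collection of (reference, test) area pairs into a bundle."""
    params = params or AnalysisParams()
    rows, failures = [], []
    for sim in sims:
        try:
            res = analyze_area(sim.reference, sim.test, params)
        except (AnalysisError, ValueError) as exc:
            log.warning("area %s/%d skipped: %s", sim.well_id, sim.area_id, exc)
            failures.append(
                dict(well=sim.well_id, area=sim.area_id, reason=str(exc))
            )
            continue
        rows.append(
            dict(
                well=sim.well_id,
                area=sim.area_id,
                concentration=sim.concentration,
                slope_all=res.slope.slope_all,
                slope_neg=res.slope.slope_neg,
                slope_pos=res.slope.slope_pos,
                stderr=res.slope.stderr,
                n_pairs=res.slope.n_pairs,
                gd_gc=res.gd_gc,
                rectification_index=res.rectification,
                shift_row=res.shift[0],
                shift_col=res.shift[1],
            )
        )
    if not rows:
        raise AnalysisError("all areas failed analysis")
    area_table = pd.DataFrame(rows)

    points: list[ConductancePoint] = []
    wrows = []
    for (well, conc), grp in area_table.groupby(["well", "concentration"], sort=True):
        vals = grp["gd_gc"].to_numpy()
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        pt = ConductancePoint(float(conc), float(vals.mean()), se, tuple(vals), well)
        points.append(pt)
        wrows.append(
            dict(
                well=well, concentration=conc, gd_gc=pt.gd_gc, se=pt.se,
                n_areas=pt.n_areas, rd_rc=1.0 / pt.gd_gc,
            )
        )
    well_table = pd.DataFrame(wrows).sort_values("concentration").reset_index(drop=True)

    crc = None
    n_conc = well_table["concentration"].loc[lambda s: s > 0].nunique()
    if n_conc >= 4:
        crc = fit_crc(
            points,
            weighted=params.weighted_crc,
            min_range=params.crc_min_range,
            bottom_fixed=params.crc_bottom_fixed,
        )

    prov = dict(provenance or {})
    prov.setdefault("software_version", __version__)
    prov["n_areas_analyzed"] = len(rows)
    prov["n_areas_failed"] = len(failures)
    return ResultBundle(area_table, well_table, crc, None, failures, prov)


# ---------------------------------------------------------------- disk I/O

PAGE_ORDER = ("reference-pre", "reference-plateau", "test-pre", "test-plateau")


def _area_stem(well_id: str, area_id: int) -> str:
    return f"{well_id}_area{area_id}"


def simulate_to_dir(config: RunConfig, outdir: str | Path) -> Path:
    """Run the simulator and write one multi-page TIFF + JSON manifest per
    sampling area, plus a run-level manifest with the full config and hash.

    Frames are stored as uint16 when noise is on (camera counts) and as
    float64 when noise is off (exact expectations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sims = simulate_passage_pair(
        config.platemap, config.drug, config.pulse, config.fieldgeom,
        config.camera, config.scene,
        antagonist=config.antagonist, agonist_conc=config.agonist_conc,
    )
    for sim in sims:
        stem = _area_stem(sim.well_id, sim.area_id)
        pages = [
            sim.reference.f_pre, sim.reference.f_plateau,
            sim.test.f_pre, sim.test.f_plateau,
        ]
        if config.scene.noise:
            pages = [np.round(p).astype(np.uint16) for p in pages]
        else:
            pages = [p.astype(np.float64) for p in pages]
        tifffile.imwrite(
            outdir / f"{stem}.tif", np.stack(pages), photometric="minisblack"
        )
        manifest = dict(
            well=sim.well_id,
            area=sim.area_id,
            drug=sim.drug,
            concentration=sim.concentration,
            seed=config.platemap.seed,
            field_direction=list(config.fieldgeom.direction),
            pulse=asdict(config.pulse),
            page_order=list(PAGE_ORDER),
            truth=sim.truth,
        )
        (outdir / f"{stem}.json").write_text(json.dumps(manifest, indent=2))
    run_manifest = dict(
        schema_version=SCHEMA_VERSION,
        config=config.to_dict(),
        config_hash=config.config_hash(),
        software_version=__version__,
        n_areas=len(sims),
    )
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, default=_jsonify)
    )
    return outdir


def load_area_stack(tif_path: str | Path) -> AreaSimulation:
    """Read one area's TIFF stack + sidecar manifest back into records."""
    tif_path = Path(tif_path)
    manifest = json.loads(tif_path.with_suffix(".json").read_text())
    pages = tifffile.imread(tif_path).astype(float)
    if pages.shape[0] != 4:
        raise ValueError(f"{tif_path.name}: expected 4 pages, got {pages.shape[0]}")
    ref = PassageRecord(pages[0], pages[1], "reference", manifest["well"], manifest["area"])
    test = PassageRecord(pages[2], pages[3], "test", manifest["well"], manifest["area"])
    return AreaSimulation(
        ref, test, manifest["well"], manifest["area"],
        manifest.get("drug", ""), manifest["concentration"], manifest.get("truth", {}),
    )


def analyze_dir(
    indir: str | Path,
    params: AnalysisParams | None = None,
    outdir: str | Path | None = None,
) -> ResultBundle:
    """Analyze every area stack in a simulate output directory."""
    indir = Path(indir)
    run_manifest_path = indir / "run_manifest.json"
    if not run_manifest_path.exists():
        raise FileNotFoundError(f"no run_manifest.json in {indir}")
    run_manifest = json.loads(run_manifest_path.read_text())
    if params is None:
        params = AnalysisParams(**run_manifest["config"]["analysis"])
    sims, failures = [], []
    for tif in sorted(indir.glob("*.tif")):
        try:
            sims.append(load_area_stack(tif))
        except (ValueError, OSError, json.JSONDecodeError) as exc:
            log.warning("stack %s unreadable, skipped: %s", tif.name, exc)
            failures.append(dict(well=tif.stem, area=None, reason=str(exc)))
    if not sims:
        raise AnalysisError("no readable area stacks")
    bundle = analyze_simulations(
        sims, params,
        provenance=dict(
            config_hash=run_manifest["config_hash"],
            seed=run_manifest["config"]["platemap"]["seed"],
        ),
    )
    bundle.failures.extend(failures)
    if outdir is not None:
        bundle.save(outdir)
    return bundle


def qc_from_bundles(bundles: list[ResultBundle]) -> dict:
    """NIH consistency report treating each bundle as one plate of curves.

    Each bundle's well table supplies one curve (rows grouped by plate row
    letter when several rows are present)."""
    plates = []
    for b in bundles:
        wt = b.well_table.sort_values("concentration")
        rows = sorted({w[0] for w in wt["well"]})
        conc = np.sort(wt["concentration"].unique())
        curves, ec50s = [], []
        for r in rows:
            sub = wt[wt["well"].str.startswith(r)].sort_values("concentration")
            if len(sub) != len(conc):
                continue
            curves.append(sub["gd_gc"].to_numpy())
            ec50s.append(b.crc.ec50 if b.crc is not None and not b.crc.flat else np.nan)
        if curves:
            plates.append(
                PlateCurves(conc, np.vstack(curves), np.asarray(ec50s))
            )
    return consistency_report(plates)


def score_bundle(bundle: ResultBundle, manifest: dict) -> dict:
    """Relative recovery errors of the bundle against simulator ground truth.

    ``manifest`` is the run manifest written by :func:`simulate_to_dir`; a
    config-hash mismatch means the bundle was produced from different inputs
    and is an error.
    """
    if "config_hash" not in manifest:
        raise ValueError("manifest missing ground truth (config_hash)")
    bundle_hash = bundle.provenance.get("config_hash")
    if bundle_hash is not None and bundle_hash != manifest["config_hash"]:
        raise ValueError("manifest mismatch: bundle from a different config")
    drug = manifest["config"]["drug"]
    report: dict = {"config_hash": manifest["config_hash"]}
    if bundle.crc is not None and not bundle.crc.flat:
        report["ec50_true"] = drug["ec50"]
        report["ec50_recovered"] = bundle.crc.ec50
        report["ec50_relative_error"] = abs(bundle.crc.ec50 / drug["ec50"] - 1.0)
        report["hill_true"] = drug["hill"]
        report["hill_recovered"] = bundle.crc.hill
        report["hill_relative_error"] = abs(bundle.crc.hill / drug["hill"] - 1.0)
    # slope recovery per concentration: truth Gd/Gc is the configured fold
    from .biophysics import DrugModel as _DM, drug_conductance_fold as _fold

    dm = _DM(**{k: v for k, v in drug.items()})
    errs = []
    for _, row in bundle.well_table.iterrows():
        g_true = _fold(row["concentration"], dm)
        errs.append(abs(row["gd_gc"] / g_true - 1.0))
    report["gd_gc_max_relative_error"] = float(np.max(errs)) if errs else None
    return report
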