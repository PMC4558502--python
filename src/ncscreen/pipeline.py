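"""End-to-end orchestration: simulate -> segment -> quantify -> call hits.

``run_screen`` drives the whole analysis from a single :class:`RunConfig`:
optionally simulate a screen to disk, then walk the plate map, segment
every field, measure per-cell ratios, aggregate to wells, compute plate
QC (Z'-factor, death-siRNA transfection check), call per-replicate
3-sigma hits and combine them into final 2-of-3 calls. All tables are
written as UTF-8 comma-separated CSV with a mandatory header and ratios
at 6 significant digits, so a rerun with the same config and seed is
byte-identical. Unreadable fields are logged to the QC report without
aborting the screen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .quantify import cells_to_frame, measure_cells
from .segment import RingParams, build_cell_regions, segment_nuclei
from .simgen import (
    KnockdownEffect,
    PlateLayout,
    PLATEMAP_COLUMNS,
    SimConfig,
    generate_plate_layout,
    simulate_screen,
)
from .screenstats import (
    EXCLUDE_NO_IMAGE,
    ScreenStats,
    WELL_COLUMNS,
    call_hits,
    compute_zprime,
    replicate_concordance,
    replicate_correlation,
    summarize_well,
    transfection_qc,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """Raised when a screen run cannot produce any evaluable well."""


@dataclass
class LayoutSpec:
    """Sizing of a simulated screen layout."""

    n_library_genes: int = 88
    n_plates: int = 1
    n_replicates: int = 3
    wells_per_plate: int = 384
    controls_per_plate: dict[str, int] | None = None


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Either ``screen_dir`` points at an existing on-disk screen
    (images + platemap.csv), or ``sim``/``layout`` describe a screen to
    simulate first. Every parameter has a default; the merged config is
    echoed to the output directory.
    """

    out_dir: str = "results"
    seed: int = 0
    screen_dir: str | None = None
    sim: SimConfig | None = None
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    planted_hits: list[KnockdownEffect] = field(default_factory=list)
    fields_per_well: int = 1
    # segmentation
    min_area: int = 30
    max_area: int = 5000
    exclude_border: bool = True
    # ring geometry
    ring_gap: float = 3.0
    ring_width: float = 5.0
    # quantification
    background_subtract: bool = False
    exclude_saturated: bool = True
    # screen statistics
    min_cells: int = 20
    k_sigma: float = 3.0
    min_reps: int = 2
    aggregator: str = "mean"
    efficiency_floor: float = 0.5
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim else None
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        d = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config schema violation: unknown keys {sorted(unknown)}")
        if d.get("sim") is not None and not isinstance(d["sim"], SimConfig):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if d.get("layout") is not None and not isinstance(d["layout"], LayoutSpec):
            lay = dict(d["layout"])
            lay_known = {f.name for f in dataclasses.fields(LayoutSpec)}
            bad = set(lay) - lay_known
            if bad:
                raise ValueError(f"config schema violation: unknown layout keys {sorted(bad)}")
            d["layout"] = LayoutSpec(**lay)
        if d.get("planted_hits"):
            d["planted_hits"] = [
                h if isinstance(h, KnockdownEffect) else KnockdownEffect(**h)
                for h in d["planted_hits"]
            ]
        cfg = cls(**d)
        if cfg.aggregator not in ("mean", "median"):
            raise ValueError("config schema violation: aggregator must be mean|median")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config schema violation: top level must be a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ScreenResult:
    """Paths to the output tables plus the run manifest."""

    out_dir: Path
    cells_csv: Path
    wells_csv: Path
    stats_csv: Path
    hits_csv: Path
    qc_csv: Path
    manifest: dict


def read_platemap(path: str | Path) -> PlateLayout:
    """Read and validate a plate-map CSV.

    The header must match the canonical column set exactly; role and
    treatment vocabularies are closed and case-sensitive, and offending
    rows are cited by number (header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PLATEMAP_COLUMNS:
        raise ValueError(
            f"malformed plate map {path.name}: header {list(df.columns)} "
            f"!= {PLATEMAP_COLUMNS}"
        )
    if df.empty:
        raise ValueError(f"malformed plate map {path.name}: no data rows")
    from .simgen import ROLES, TREATMENTS

    for col, vocab in (("role", ROLES), ("treatment", TREATMENTS)):
        bad = ~df[col].isin(vocab)
        if bad.any():
            idx = int(df.index[bad][0])
            raise ValueError(
                f"malformed plate map {path.name}: unknown {col} "
                f"{df.loc[idx, col]!r} at row {idx + 2} (case-sensitive; "
                f"expected one of {vocab})"
            )
    dup = df[["plate_id", "replicate_id", "well_id"]].duplicated()
    if dup.any():
        idx = int(df.index[dup][0])
        raise ValueError(
            f"malformed plate map {path.name}: duplicate (plate, replicate, well) "
            f"at row {idx + 2}"
        )
    return PlateLayout(df)


def _analyze_field(nuc_path: Path, prot_path: Path, cfg: RunConfig, well_id: str):
    nuc = tifffile.imread(nuc_path)
    prot = tifffile.imread(prot_path)
    mask = segment_nuclei(nuc, min_area=cfg.min_area, max_area=cfg.max_area,
                          exclude_border=cfg.exclude_border)
    regions = build_cell_regions(mask, RingParams(cfg.ring_gap, cfg.ring_width))
    return measure_cells(prot, regions, well_id=well_id,
                         background_subtract=cfg.background_subtract,
                         exclude_saturated=cfg.exclude_saturated)


def analyze_screen(screen_dir: str | Path, cfg: RunConfig) -> ScreenResult:
    """Analyze an on-disk screen tree into the four result tables."""
    screen = Path(screen_dir)
    layout = read_platemap(screen / "platemap.csv")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cell_frames: list[pd.DataFrame] = []
    well_rows: list[dict] = []
    qc_rows: list[dict] = []
    raw_counts: dict[tuple[str, str, str], int] = {}

    for well in layout.wells():
        records = []
        n_missing = 0
        for k in range(1, cfg.fields_per_well + 1):
            stem = screen / well.replicate_id / well.plate_id / f"{well.well_id}_f{k}"
            nuc_p, prot_p = Path(f"{stem}_nuc.tif"), Path(f"{stem}_prot.tif")
            if not (nuc_p.exists() and prot_p.exists()):
                n_missing += 1
                qc_rows.append({"stage": "read", "plate_id": well.plate_id,
                                "replicate_id": well.replicate_id,
                                "well_id": well.well_id,
                                "event": f"missing field {k}"})
                continue
            try:
                recs = _analyze_field(nuc_p, prot_p, cfg, well.well_id)
            except (OSError, ValueError) as exc:
                qc_rows.append({"stage": "segment", "plate_id": well.plate_id,
                                "replicate_id": well.replicate_id,
                                "well_id": well.well_id,
                                "event": f"unreadable field {k}: {exc}"})
                continue
            records.extend(recs)
            cell_frames.append(cells_to_frame(recs, plate_id=well.plate_id,
                                              replicate_id=well.replicate_id,
                                              field_index=k))
        key = (well.replicate_id, well.plate_id, well.well_id)
        raw_counts[key] = len(records)
        meta = dict(plate_id=well.plate_id, replicate_id=well.replicate_id,
                    well_id=well.well_id, gene_id=well.gene_id,
                    role=well.role, treatment=well.treatment)
        if n_missing == cfg.fields_per_well:
            well_rows.append(dict(meta, n_cells_evaluable=0, well_ratio=np.nan,
                                  excluded=True, exclude_reason=EXCLUDE_NO_IMAGE))
            continue
        summary = summarize_well(records, min_cells=cfg.min_cells,
                                 aggregator=cfg.aggregator, **meta)
        well_rows.append(dataclasses.asdict(summary))
        log.info("well %s/%s/%s: %d evaluable cells, ratio %s",
                 well.replicate_id, well.plate_id, well.well_id,
                 summary.n_cells_evaluable,
                 f"{summary.well_ratio:.3f}" if np.isfinite(summary.well_ratio) else "n/a")

    wells = pd.DataFrame(well_rows, columns=WELL_COLUMNS)
    evaluable = wells[~wells["excluded"].astype(bool)]
    if evaluable.empty:
        raise PipelineError("no evaluable well in the entire screen")

    # plate-level QC: Z' (vehicle vs stress negative controls) + transfection
    stats_rows: list[dict] = []
    hit_frames: list[pd.DataFrame] = []
    for rep, rep_wells in wells.groupby("replicate_id", sort=True):
        zprimes: dict[str, float] = {}
        for plate, plate_wells in rep_wells.groupby("plate_id", sort=True):
            neg = plate_wells[(plate_wells["role"] == "neg_ctrl")
                              & ~plate_wells["excluded"].astype(bool)]
            pos_arm = neg[neg["treatment"] == "vehicle"]["well_ratio"]
            neg_arm = neg[neg["treatment"] == "stress"]["well_ratio"]
            try:
                zprimes[plate] = compute_zprime(pos_arm, neg_arm)
            except ValueError as exc:
                qc_rows.append({"stage": "zprime", "plate_id": plate,
                                "replicate_id": rep, "well_id": "",
                                "event": str(exc)})
            death = [raw_counts[(rep, plate, w)] for w in
                     plate_wells[plate_wells["role"] == "death_ctrl"]["well_id"]]
            ctrl = [raw_counts[(rep, plate, w)] for w in
                    neg[neg["treatment"] == "stress"]["well_id"]]
            if death and ctrl:
                try:
                    tqc = transfection_qc(death, ctrl, cfg.efficiency_floor)
                    qc_rows.append({"stage": "transfection", "plate_id": plate,
                                    "replicate_id": rep, "well_id": "",
                                    "event": f"efficiency={tqc.efficiency:.4g}"
                                             f" flagged={tqc.flagged}"})
                except ValueError as exc:
                    qc_rows.append({"stage": "transfection", "plate_id": plate,
                                    "replicate_id": rep, "well_id": "",
                                    "event": str(exc)})
        try:
            stats, flagged = call_hits(rep_wells, k_sigma=cfg.k_sigma,
                                       replicate_id=str(rep))
        except ValueError as exc:
            qc_rows.append({"stage": "hits", "plate_id": "", "replicate_id": rep,
                            "well_id": "", "event": str(exc)})
            continue
        stats.zprime_per_plate = zprimes
        stats_rows.append({
            "replicate_id": stats.replicate_id, "mean_m": stats.mean_m,
            "sd_sigma": stats.sd_sigma, "k_sigma": stats.k_sigma,
            "hit_threshold": stats.hit_threshold, "n_wells": stats.n_wells,
            "zprime_per_plate": ";".join(f"{p}={z:.6g}" for p, z in sorted(zprimes.items())),
        })
        hit_frames.append(flagged[flagged["role"] == "library"])

    hits = pd.DataFrame()
    if hit_frames:
        long = pd.concat(hit_frames, ignore_index=True)
        hits = replicate_concordance(long, min_reps=cfg.min_reps)
        reps = sorted(long["replicate_id"].unique())
        for a, b in zip(reps, reps[1:]):
            try:
                r, _ = replicate_correlation(long[long["replicate_id"] == a],
                                             long[long["replicate_id"] == b])
                qc_rows.append({"stage": "correlation", "plate_id": "",
                                "replicate_id": f"{a}/{b}", "well_id": "",
                                "event": f"pearson_r={r:.6g}"})
            except ValueError as exc:
                qc_rows.append({"stage": "correlation", "plate_id": "",
                                "replicate_id": f"{a}/{b}", "well_id": "",
                                "event": str(exc)})

    cells = (pd.concat(cell_frames, ignore_index=True) if cell_frames
             else pd.DataFrame())
    qc = pd.DataFrame(qc_rows, columns=["stage", "plate_id", "replicate_id",
                                        "well_id", "event"])
    stats_df = pd.DataFrame(stats_rows, columns=[
        "replicate_id", "mean_m", "sd_sigma", "k_sigma", "hit_threshold",
        "n_wells", "zprime_per_plate"])

    paths = {
        "cells_csv": out / "cells.csv",
        "wells_csv": out / "wells.csv",
        "stats_csv": out / "screen_stats.csv",
        "hits_csv": out / "hits.csv",
        "qc_csv": out / "qc_report.csv",
    }
    cells.to_csv(paths["cells_csv"], index=False, float_format=FLOAT_FORMAT)
    wells.to_csv(paths["wells_csv"], index=False, float_format=FLOAT_FORMAT)
    stats_df.to_csv(paths["stats_csv"], index=False, float_format=FLOAT_FORMAT)
    hits.to_csv(paths["hits_csv"], index=False, float_format=FLOAT_FORMAT)
    qc.to_csv(paths["qc_csv"], index=False)

    manifest = {
        "tool": "ncscreen",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "screen_dir": str(screen),
        "n_wells": int(len(wells)),
        "n_evaluable_wells": int(len(evaluable)),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "effective_config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return ScreenResult(out_dir=out, manifest=manifest, **paths)


def run_screen(cfg: RunConfig) -> ScreenResult:
    """Execute the full pipeline per the config: simulate if no screen
    directory is given, then analyze."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    screen_dir = cfg.screen_dir
    if screen_dir is None:
        sim = cfg.sim if cfg.sim is not None else SimConfig()
        sim = dataclasses.replace(sim, rng_seed=cfg.seed)
        lay = cfg.layout
        layout = generate_plate_layout(
            lay.n_library_genes, lay.n_plates, lay.n_replicates,
            controls_per_plate=lay.controls_per_plate,
            wells_per_plate=lay.wells_per_plate, seed=cfg.seed)
        screen_dir = Path(cfg.out_dir) / "screen"
        simulate_screen(sim, layout, planted_hits=cfg.planted_hits,
                        fields_per_well=cfg.fields_per_well, out_dir=screen_dir)
    return analyze_screen(screen_dir, cfg)
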