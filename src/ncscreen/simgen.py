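"""Synthetic two-channel screen generator with per-cell ground truth.

Emulates a 384-well high-content RNAi screen in which a shuttling
RNA-binding protein relocates from the nucleus to the cytoplasm under
hypertonic stress. Each well field is rendered as a pair of 16-bit
grayscale images — a nuclear stain channel and a protein
immunofluorescence channel — together with a ground-truth table giving
every cell's geometry, total protein content, cytoplasmic fraction and
the analytic nuclear/cytoplasmic mean-intensity ratio the measurement
stage should recover.

Cells are non-overlapping disks (nuclei) inside axis-aligned concentric
ellipses (cytoplasm). Protein is split between the two compartments
according to a per-cell cytoplasmic fraction ``f_cyt`` sampled
logit-normally around the condition mean: the vehicle baseline for
DMEM-treated wells, the stress level for sorbitol-treated wells, and an
intermediate value for wells whose gene knockdown attenuates the stress
response. Intensities are uniform within each compartment (region total
divided by region pixel count) on top of a flat background, optionally
degraded by Poisson shot noise, Gaussian read noise and 16-bit
quantization.

Every generator path is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import string
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: Closed role vocabulary for plate-map wells. ``empty`` marks unused
#: positions on a partially filled plate; such wells are never rendered.
ROLES = ("library", "neg_ctrl", "gfp_ctrl", "death_ctrl", "empty")
TREATMENTS = ("stress", "vehicle")

U16_MAX = 65535
ROW_LETTERS = string.ascii_uppercase[:16]  # A..P, 384-well convention
N_COLS = 24
PLATEMAP_COLUMNS = ["plate_id", "replicate_id", "well_id", "gene_id", "role", "treatment"]


def well_name(index: int) -> str:
    """Row-major well name on a 384-well grid: 0 -> 'A01', 383 -> 'P24'."""
    if not 0 <= index < 16 * N_COLS:
        raise ValueError(f"well index {index} outside the 384-well grid")
    return f"{ROW_LETTERS[index // N_COLS]}{index % N_COLS + 1:02d}"


# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generative parameters for one screen simulation.

    Intensities are arbitrary fluorescence units on the 16-bit scale;
    lengths are pixels. ``cells_per_field`` is the Poisson mean of the
    number of cells attempted per field; ``f_cyt_baseline`` and
    ``f_cyt_stress`` are the condition means of the cytoplasmic protein
    fraction, jittered per cell with a logit-normal of spread
    ``f_cyt_sd`` (approximate standard deviation on the fraction
    scale). ``death_survival`` scales ``cells_per_field`` in
    death-siRNA control wells, emulating successful transfection.
    ``quantize_16bit`` rounds and clips rendered images to uint16;
    disable it for exact-arithmetic renders (on-disk screens are always
    written as 16-bit TIFF regardless).
    """

    image_width: int = 512
    image_height: int = 512
    cells_per_field: float = 50.0
    nucleus_radius_mean: float = 9.0
    nucleus_radius_sd: float = 1.2
    cyto_radius_extra_min: float = 8.0
    cyto_radius_extra_max: float = 13.0
    total_protein_mean: float = 2.0e5
    total_protein_sd: float = 4.0e4
    f_cyt_baseline: float = 0.15
    f_cyt_stress: float = 0.60
    f_cyt_sd: float = 0.05
    background_level: float = 100.0
    nuclear_stain_level: float = 30000.0
    noise_sd: float = 5.0
    shot_noise: bool = True
    quantize_16bit: bool = True
    death_survival: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("image dimensions must be >= 64 pixels")
        if not (0.0 <= self.f_cyt_baseline <= self.f_cyt_stress <= 1.0):
            raise ValueError(
                "require 0 <= f_cyt_baseline <= f_cyt_stress <= 1, got "
                f"{self.f_cyt_baseline} / {self.f_cyt_stress}"
            )
        for name in (
            "nucleus_radius_mean", "nucleus_radius_sd", "cyto_radius_extra_min",
            "cyto_radius_extra_max", "total_protein_mean", "total_protein_sd",
            "background_level", "nuclear_stain_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cyto_radius_extra_max < self.cyto_radius_extra_min:
            raise ValueError("cyto_radius_extra_max < cyto_radius_extra_min")
        if self.cells_per_field < 0 or self.noise_sd < 0 or self.f_cyt_sd < 0:
            raise ValueError("cells_per_field, noise_sd and f_cyt_sd must be >= 0")
        if not (0.0 <= self.death_survival <= 1.0):
            raise ValueError("death_survival must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class KnockdownEffect:
    """Attenuation of the stress-induced translocation by one knockdown.

    ``effect`` is the fraction of the stress shift that is blocked:
    0 leaves the stress response intact, 1 makes the cell behave as if
    vehicle-treated.
    """

    gene_id: str
    effect: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError(f"effect must lie in [0, 1], got {self.effect}")


@dataclass(frozen=True)
class WellSpec:
    """Identity of one well in one replicate of the screen."""

    plate_id: str
    replicate_id: str
    well_id: str
    gene_id: str = ""
    role: str = "library"
    treatment: str = "stress"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )


@dataclass(frozen=True)
class GroundTruthCell:
    """Per-cell generative truth for one rendered field.

    ``expected_ratio`` is the analytic nuclear/cytoplasmic
    mean-intensity ratio ((1-f)T/A_nuc + b) / (fT/A_cyt + b) computed
    with the rasterized region pixel counts, i.e. the value a perfect
    segmentation and background-free measurement should recover.
    """

    cell_id: int
    well_id: str
    center_row: float
    center_col: float
    nucleus_radius: float
    cyto_extra_row: float
    cyto_extra_col: float
    total_protein: float
    f_cyt: float
    nuc_area: int
    cyto_area: int
    expected_ratio: float
    clipped: bool


@dataclass
class PlateLayout:
    """Well -> (gene, role, treatment) map for a multi-plate screen.

    Thin wrapper around a :class:`pandas.DataFrame` with the plate-map
    columns; one row per (plate, replicate, well).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATEMAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"plate layout missing columns {missing}")
        self.table = self.table[PLATEMAP_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        bad_role = ~self.table["role"].isin(ROLES)
        if bad_role.any():
            row = int(self.table.index[bad_role][0])
            raise ValueError(
                f"unknown role {self.table.loc[row, 'role']!r} at layout row {row}"
            )
        bad_treat = ~self.table["treatment"].isin(TREATMENTS)
        if bad_treat.any():
            row = int(self.table.index[bad_treat][0])
            raise ValueError(
                f"unknown treatment {self.table.loc[row, 'treatment']!r} at layout row {row}"
            )
        key = self.table[["plate_id", "replicate_id", "well_id"]]
        dup = key.duplicated()
        if dup.any():
            first = key[dup].iloc[0].tolist()
            raise ValueError(f"duplicate (plate, replicate, well) entry {tuple(first)}")

    @property
    def library_genes(self) -> list[str]:
        lib = self.table[self.table["role"] == "library"]
        return sorted(lib["gene_id"].unique())

    @property
    def replicates(self) -> list[str]:
        return sorted(self.table["replicate_id"].unique())

    def wells(self, include_empty: bool = False) -> Iterable[WellSpec]:
        for row in self.table.itertuples(index=False):
            if row.role == "empty" and not include_empty:
                continue
            yield WellSpec(row.plate_id, row.replicate_id, row.well_id,
                           row.gene_id, row.role, row.treatment)

    def __len__(self) -> int:
        return len(self.table)


DEFAULT_CONTROLS = {"neg_ctrl": 8, "gfp_ctrl": 2, "death_ctrl": 2}


def generate_plate_layout(
    n_library_genes: int,
    n_plates: int,
    n_replicates: int,
    controls_per_plate: Mapping[str, int] | None = None,
    wells_per_plate: int = 384,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> PlateLayout:
    """Lay out a library of siRNA pools plus controls on replicate plates.

    Every library gene appears exactly once per replicate; replicate
    plates share the same arrangement (reverse-transfected plate
    copies). Each plate carries the requested control wells:
    non-targeting negative controls split between stress and vehicle
    (DMEM) treatment, GFP-targeting controls and death-siRNA
    transfection controls (both stress-treated). Unused positions are
    emitted with role ``empty``. Well positions are shuffled
    deterministically from ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if not 1 <= wells_per_plate <= 384:
        raise ValueError("wells_per_plate must lie in [1, 384]")
    controls = dict(DEFAULT_CONTROLS if controls_per_plate is None else controls_per_plate)
    unknown = set(controls) - {"neg_ctrl", "gfp_ctrl", "death_ctrl"}
    if unknown:
        raise ValueError(f"unknown control roles {sorted(unknown)}")
    n_controls = sum(controls.values())
    if n_controls > wells_per_plate:
        raise ValueError(
            f"{n_controls} control wells do not fit on a {wells_per_plate}-well plate"
        )
    lib_per_plate = wells_per_plate - n_controls
    capacity = n_plates * lib_per_plate
    if n_library_genes > capacity:
        raise ValueError(
            f"capacity exceeded: {n_library_genes} library genes need "
            f"{n_library_genes - capacity} more wells than the {n_plates} plate(s) "
            f"provide ({capacity} library wells)"
        )
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:04d}" for i in range(n_library_genes)]
    elif len(gene_ids) != n_library_genes:
        raise ValueError("gene_ids length must equal n_library_genes")

    rng = np.random.default_rng(seed)
    rows = []
    gene_cursor = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        positions = [well_name(i) for i in range(wells_per_plate)]
        order = rng.permutation(wells_per_plate)
        shuffled = [positions[i] for i in order]
        plan: list[tuple[str, str, str]] = []  # (gene_id, role, treatment)
        n_neg = controls.get("neg_ctrl", 0)
        for j in range(n_neg):
            treat = "vehicle" if j < n_neg // 2 else "stress"
            plan.append(("CTRL_NT", "neg_ctrl", treat))
        for _ in range(controls.get("gfp_ctrl", 0)):
            plan.append(("CTRL_GFP", "gfp_ctrl", "stress"))
        for _ in range(controls.get("death_ctrl", 0)):
            plan.append(("CTRL_DEATH", "death_ctrl", "stress"))
        n_genes_here = min(lib_per_plate, n_library_genes - gene_cursor)
        for g in range(n_genes_here):
            plan.append((gene_ids[gene_cursor + g], "library", "stress"))
        gene_cursor += n_genes_here
        while len(plan) < wells_per_plate:
            plan.append(("", "empty", "stress"))
        for well, (gene, role, treat) in zip(shuffled, plan):
            rows.append((plate_id, well, gene, role, treat))

    records = []
    for r in range(n_replicates):
        rep_id = f"R{r + 1}"
        for plate_id, well, gene, role, treat in rows:
            records.append((plate_id, rep_id, well, gene, role, treat))
    table = pd.DataFrame.from_records(records, columns=PLATEMAP_COLUMNS)
    table = table.sort_values(["replicate_id", "plate_id", "well_id"], kind="stable")
    return PlateLayout(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Analytic ratio model
# ---------------------------------------------------------------------------

def expected_ratio(f_cyt: float, total_protein: float, nuc_area: int,
                   cyto_area: int, background: float) -> float:
    """Analytic nuclear/cytoplasmic mean-intensity ratio of one cell.

    Strictly decreasing in ``f_cyt`` for fixed protein, areas and
    background: more cytoplasmic protein lowers the nuclear mean and
    raises the cytoplasmic mean simultaneously.
    """
    nuc = (1.0 - f_cyt) * total_protein / nuc_area + background
    cyt = f_cyt * total_protein / cyto_area + background
    return nuc / cyt


def condition_f_cyt(config: SimConfig, treatment: str, effect: float = 0.0) -> float:
    """Condition-mean cytoplasmic fraction for a well.

    Vehicle wells sit at the baseline; stress wells at the stress level
    attenuated toward baseline by the knockdown ``effect``.
    """
    if treatment == "vehicle":
        return config.f_cyt_baseline
    return config.f_cyt_stress - effect * (config.f_cyt_stress - config.f_cyt_baseline)


def _disk_area(radius: float) -> int:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return int(np.count_nonzero(yy * yy + xx * xx <= radius * radius))


def _ellipse_minus_disk_area(radius: float, extra: float) -> int:
    a = radius + extra
    r = int(np.ceil(a))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = (yy / a) ** 2 + (xx / a) ** 2 <= 1.0
    nuc = yy * yy + xx * xx <= radius * radius
    return int(np.count_nonzero(inside & ~nuc))


def analytic_condition_ratio(config: SimConfig, treatment: str, effect: float = 0.0) -> float:
    """Expected ratio of a nominal cell (mean geometry) in a condition."""
    r = config.nucleus_radius_mean
    extra = 0.5 * (config.cyto_radius_extra_min + config.cyto_radius_extra_max)
    a_nuc = _disk_area(r)
    a_cyt = _ellipse_minus_disk_area(r, extra)
    f = condition_f_cyt(config, treatment, effect)
    return expected_ratio(f, config.total_protein_mean, a_nuc, a_cyt,
                          config.background_level)


def _sample_logit_normal(rng: np.random.Generator, mean: float, sd_frac: float,
                         size: int) -> np.ndarray:
    """Sample fractions in (0,1) around ``mean`` with ~``sd_frac`` spread.

    Normal on the logit scale with the delta-method scaling
    sd_logit = sd_frac / (mean (1-mean)); degenerate at mean 0 or 1.
    """
    if sd_frac == 0.0 or mean <= 0.0 or mean >= 1.0:
        return np.full(size, mean)
    mu = np.log(mean / (1.0 - mean))
    sd = sd_frac / (mean * (1.0 - mean))
    z = rng.normal(mu, sd, size)
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------

_PLACEMENT_ATTEMPTS = 200


def _field_rng(config: SimConfig, well: WellSpec, field_index: int = 1) -> np.random.Generator:
    key = f"{well.plate_id}|{well.replicate_id}|{well.well_id}|{field_index}".encode()
    return np.random.default_rng([config.rng_seed, zlib.crc32(key)])


def render_field(
    config: SimConfig,
    well: WellSpec,
    effects: Sequence[KnockdownEffect] = (),
    rng: np.random.Generator | None = None,
    field_index: int = 1,
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthCell]]:
    """Render one well field: nuclear channel, protein channel, truth.

    Nuclei are non-overlapping filled disks; each cell's cytoplasm
    ellipse is kept disjoint from its neighbours' (they may touch), so
    an annular cytoplasm probe up to ``cyto_radius_extra_min`` pixels
    beyond the nucleus samples only that cell's compartment. Cells that
    cannot be placed within a bounded number of rejection attempts are
    dropped with a logged warning. Returns uint16 images when
    ``config.quantize_16bit`` (clipping recorded per cell in the truth
    table), float64 otherwise.
    """
    config.validate()
    if rng is None:
        rng = _field_rng(config, well, field_index)
    H, W = config.image_height, config.image_width
    effect = 0.0
    for e in effects:
        if e.gene_id == well.gene_id:
            effect = e.effect
    f_mean = condition_f_cyt(config, well.treatment, effect)

    mean_cells = config.cells_per_field
    if well.role == "death_ctrl":
        mean_cells *= config.death_survival
    n_target = int(rng.poisson(mean_cells)) if mean_cells > 0 else 0

    # Geometry with rejection placement: disjoint cytoplasm footprints.
    placed: list[tuple[float, float, float, float, float, float]] = []
    n_failed = 0
    for _ in range(n_target):
        radius = max(3.0, rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd))
        er, ec = rng.uniform(config.cyto_radius_extra_min,
                             config.cyto_radius_extra_max, 2)
        reach = radius + max(er, ec)
        margin = reach + 1.0
        if 2 * margin >= min(H, W):
            n_failed += 1
            continue
        ok = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(margin, H - 1 - margin)
            cx = rng.uniform(margin, W - 1 - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (reach + pr + 1.0) ** 2
                   for py, px, pr in ((p[0], p[1], p[2] + max(p[3], p[4])) for p in placed)):
                ok = True
                break
        if ok:
            placed.append((cy, cx, radius, er, ec, reach))
        else:
            n_failed += 1
    if n_failed:
        log.warning("field %s/%s/%s: %d of %d cells could not be placed",
                    well.plate_id, well.replicate_id, well.well_id, n_failed, n_target)

    f_vals = _sample_logit_normal(rng, f_mean, config.f_cyt_sd, len(placed))
    t_vals = np.maximum(1.0, rng.normal(config.total_protein_mean,
                                        config.total_protein_sd, len(placed)))

    nuc_img = np.full((H, W), float(config.background_level))
    prot_img = np.full((H, W), float(config.background_level))
    cell_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    truth: list[GroundTruthCell] = []
    for i, (cy, cx, radius, er, ec, reach) in enumerate(placed):
        r_int = int(np.ceil(reach)) + 1
        r0, r1 = int(np.floor(cy)) - r_int, int(np.floor(cy)) + r_int + 1
        c0, c1 = int(np.floor(cx)) - r_int, int(np.floor(cx)) + r_int + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, H), min(c1, W)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        nuc_mask = dy * dy + dx * dx <= radius * radius
        ell = (dy / (radius + er)) ** 2 + (dx / (radius + ec)) ** 2 <= 1.0
        cyt_mask = ell & ~nuc_mask
        a_nuc = int(np.count_nonzero(nuc_mask))
        a_cyt = int(np.count_nonzero(cyt_mask))
        if a_nuc == 0 or a_cyt == 0:
            continue
        f, T = float(f_vals[i]), float(t_vals[i])
        nuc_density = (1.0 - f) * T / a_nuc
        cyt_density = f * T / a_cyt
        prot_img[r0:r1, c0:c1][nuc_mask] += nuc_density
        prot_img[r0:r1, c0:c1][cyt_mask] += cyt_density
        nuc_img[r0:r1, c0:c1][nuc_mask] += config.nuclear_stain_level
        cell_pixels.append((nuc_mask, (r0, r1, c0, c1)))
        truth.append(GroundTruthCell(
            cell_id=len(truth) + 1,
            well_id=well.well_id,
            center_row=cy, center_col=cx,
            nucleus_radius=radius,
            cyto_extra_row=er, cyto_extra_col=ec,
            total_protein=T, f_cyt=f,
            nuc_area=a_nuc, cyto_area=a_cyt,
            expected_ratio=expected_ratio(f, T, a_nuc, a_cyt, config.background_level),
            clipped=False,
        ))

    if config.shot_noise:
        nuc_img = rng.poisson(nuc_img).astype(float)
        prot_img = rng.poisson(prot_img).astype(float)
    if config.noise_sd > 0:
        nuc_img = nuc_img + rng.normal(0.0, config.noise_sd, nuc_img.shape)
        prot_img = prot_img + rng.normal(0.0, config.noise_sd, prot_img.shape)

    if config.quantize_16bit:
        over = prot_img > U16_MAX
        if over.any():
            for i, (mask, (r0, r1, c0, c1)) in enumerate(cell_pixels):
                region = over[r0:r1, c0:c1]
                cy, cx, radius, er, ec, reach = placed[i]
                yy, xx = np.mgrid[r0:r1, c0:c1]
                footprint = ((yy - cy) / (radius + er)) ** 2 + ((xx - cx) / (radius + ec)) ** 2 <= 1.0
                if (region & footprint).any():
                    truth[i] = dataclasses.replace(truth[i], clipped=True)
        nuc_img = np.clip(np.rint(nuc_img), 0, U16_MAX).astype(np.uint16)
        prot_img = np.clip(np.rint(prot_img), 0, U16_MAX).astype(np.uint16)
    return nuc_img, prot_img, truth


# ---------------------------------------------------------------------------
# Whole-screen simulation
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "plate_id", "replicate_id", "well_id", "field", "cell_id",
    "center_row", "center_col", "nucleus_radius", "cyto_extra_row",
    "cyto_extra_col", "total_protein", "f_cyt", "nuc_area", "cyto_area",
    "expected_ratio", "clipped",
]


def simulate_screen(
    config: SimConfig,
    layout: PlateLayout,
    planted_hits: Sequence[KnockdownEffect] = (),
    fields_per_well: int = 1,
    out_dir: str | Path = "screen",
) -> Path:
    """Render a whole screen to disk with plate map, truth and manifest.

    Output tree::

        <out>/<replicate>/<plate>/<well>_f<k>_{nuc,prot}.tif   (uint16)
        <out>/platemap.csv
        <out>/truth_cells.csv
        <out>/manifest.json        (seed + config echo + content hash)
    """
    config.validate()
    if fields_per_well < 1:
        raise ValueError("fields_per_well must be >= 1")
    library = set(layout.library_genes)
    for hit in planted_hits:
        if hit.gene_id not in library:
            raise ValueError(f"planted hit {hit.gene_id!r} is not a library gene in the layout")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")  # fail before any rendering if the path is unwritable
    probe.unlink()

    render_cfg = dataclasses.replace(config, quantize_16bit=True)
    truth_rows: list[tuple] = []
    n_fields = 0
    for well in layout.wells():
        well_dir = out / well.replicate_id / well.plate_id
        well_dir.mkdir(parents=True, exist_ok=True)
        for k in range(1, fields_per_well + 1):
            rng = _field_rng(render_cfg, well, k)
            nuc, prot, truth = render_field(render_cfg, well, planted_hits, rng=rng)
            stem = f"{well.well_id}_f{k}"
            tifffile.imwrite(well_dir / f"{stem}_nuc.tif", nuc)
            tifffile.imwrite(well_dir / f"{stem}_prot.tif", prot)
            n_fields += 1
            for cell in truth:
                truth_rows.append((
                    well.plate_id, well.replicate_id, well.well_id, k,
                    cell.cell_id, cell.center_row, cell.center_col,
                    cell.nucleus_radius, cell.cyto_extra_row, cell.cyto_extra_col,
                    cell.total_protein, cell.f_cyt, cell.nuc_area, cell.cyto_area,
                    cell.expected_ratio, cell.clipped,
                ))

    layout.table.to_csv(out / "platemap.csv", index=False)
    truth_df = pd.DataFrame.from_records(truth_rows, columns=TRUTH_COLUMNS)
    truth_df.to_csv(out / "truth_cells.csv", index=False, float_format="%.10g")

    config_echo = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(config_echo, sort_keys=True).encode()
        + layout.table.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "seed": config.rng_seed,
        "config": config_echo,
        "fields_per_well": fields_per_well,
        "planted_hits": [dataclasses.asdict(h) for h in planted_hits],
        "n_fields": n_fields,
        "content_hash": digest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Statistic-level simulation (well ratios drawn directly)
# ---------------------------------------------------------------------------

def draw_well_ratio_screen(
    n_genes: int,
    n_replicates: int = 3,
    null_mean: float = 2.0,
    null_sd: float = 0.25,
    planted: Mapping[str, float] | None = None,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw stress-treated library well ratios directly, skipping images.

    Null genes draw a Gaussian well ratio N(null_mean, null_sd) per
    replicate; ``planted`` maps gene ids to their mean well ratio
    (drawn with the same well-level sd). Returns a wells table with the
    columns the hit-calling statistics expect.
    """
    planted = dict(planted or {})
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes {sorted(unknown)} not in the gene list")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        rep = f"R{r + 1}"
        means = np.array([planted.get(g, null_mean) for g in gene_ids])
        ratios = rng.normal(means, null_sd)
        for gene, ratio, idx in zip(gene_ids, ratios, range(n_genes)):
            rows.append(("P01", rep, well_name(idx % 384), gene, "library",
                         "stress", 100, float(ratio), False, ""))
    return pd.DataFrame.from_records(rows, columns=[
        "plate_id", "replicate_id", "well_id", "gene_id", "role", "treatment",
        "n_cells_evaluable", "well_ratio", "excluded", "exclude_reason",
    ])
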