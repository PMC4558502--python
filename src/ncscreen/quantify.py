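"""Per-cell nuclear/cytoplasmic ratio measurement and classification.

The translocation readout is the ratio of the average protein-channel
intensity over a cell's nucleus mask to the average over its
cytoplasmic ring mask. High ratios mean nuclear retention; cytoplasmic
accumulation under stress drives the ratio down. ``measure_cells``
computes raw average intensities (no background subtraction by
default); ``classify_translocation`` is a reproducible surrogate for
manual blinded counting of "cytoplasmic" cells, thresholding the ratio
at ``tau``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segment import CellRegions, QC_BORDER, QC_RING_EMPTY

log = logging.getLogger(__name__)

QC_RING_ZERO_MEAN = "ring_zero_mean"
QC_SATURATED = "saturated"

#: flags that disqualify a cell's ratio from downstream statistics
DISQUALIFYING = frozenset({QC_RING_EMPTY, QC_RING_ZERO_MEAN, QC_SATURATED, QC_BORDER})


@dataclass
class CellRecord:
    """One segmented cell's measured intensities and ratio.

    ``nc_ratio`` is NaN whenever the ring mean is zero, the ring is
    empty, or a disqualifying QC flag is set.
    """

    cell_id: int
    well_id: str
    nuc_mean: float
    ring_mean: float
    nc_ratio: float
    nuc_area: int
    ring_area: int
    centroid_row: float
    centroid_col: float
    qc_flags: tuple[str, ...] = ()

    @property
    def evaluable(self) -> bool:
        return np.isfinite(self.nc_ratio)


def measure_cells(
    protein_channel: np.ndarray,
    regions: Sequence[CellRegions],
    well_id: str = "",
    background_subtract: bool = False,
    exclude_saturated: bool = True,
    saturation_level: float | None = None,
) -> list[CellRecord]:
    """Measure nucleus and ring mean intensities for every cell.

    Means are plain arithmetic means of protein-channel pixel values
    over the respective pixel sets. Cells containing any pixel at the
    image dtype maximum (integer images; override with
    ``saturation_level``) are flagged saturated and, by default,
    excluded from ratios. Optional ``background_subtract`` removes the
    image median before measuring (off by default: the assay uses raw
    average intensities).
    """
    img = np.asarray(protein_channel)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D protein channel, got shape {img.shape}")
    if regions and regions[0].shape != img.shape:
        raise ValueError(
            f"image shape {img.shape} does not match segmentation shape {regions[0].shape}"
        )
    if saturation_level is None and np.issubdtype(img.dtype, np.integer):
        saturation_level = float(np.iinfo(img.dtype).max)
    flat = img.reshape(-1).astype(float)
    if background_subtract:
        flat = flat - float(np.median(flat))

    records: list[CellRecord] = []
    for reg in regions:
        flags = set(reg.qc_flags)
        nuc_vals = flat[reg.nucleus_idx]
        nuc_mean = float(nuc_vals.mean())
        if reg.ring_idx.size == 0:
            flags.add(QC_RING_EMPTY)
            ring_mean = np.nan
        else:
            ring_mean = float(flat[reg.ring_idx].mean())
            if ring_mean == 0.0:
                flags.add(QC_RING_ZERO_MEAN)
        if saturation_level is not None:
            raw = img.reshape(-1)
            if (raw[reg.nucleus_idx] >= saturation_level).any() or (
                reg.ring_idx.size and (raw[reg.ring_idx] >= saturation_level).any()
            ):
                flags.add(QC_SATURATED)
        disqualified = bool(flags & (DISQUALIFYING if exclude_saturated
                                     else DISQUALIFYING - {QC_SATURATED}))
        ratio = np.nan
        if not disqualified and np.isfinite(ring_mean) and ring_mean > 0:
            ratio = nuc_mean / ring_mean
        records.append(CellRecord(
            cell_id=reg.cell_id,
            well_id=well_id,
            nuc_mean=nuc_mean,
            ring_mean=float(ring_mean) if np.isfinite(ring_mean) else np.nan,
            nc_ratio=ratio,
            nuc_area=reg.nucleus_area,
            ring_area=reg.ring_area,
            centroid_row=reg.centroid[0],
            centroid_col=reg.centroid[1],
            qc_flags=tuple(sorted(flags)),
        ))
    return records


@dataclass(frozen=True)
class TranslocationResult:
    """Fraction of evaluable cells classified cytoplasmic-positive."""

    fraction: float
    n_positive: int
    n_evaluable: int


def classify_translocation(cells: Sequence[CellRecord], tau: float) -> TranslocationResult:
    """Count cells with cytoplasmic protein accumulation.

    A cell is cytoplasmic-positive iff its nuclear/cytoplasmic ratio is
    strictly below ``tau``. Raises if no cell has a defined ratio,
    naming the QC exclusions encountered.
    """
    ratios = np.array([c.nc_ratio for c in cells], dtype=float)
    evaluable = np.isfinite(ratios)
    if not evaluable.any():
        flag_counts = Counter(f for c in cells for f in c.qc_flags)
        detail = ", ".join(f"{k}={v}" for k, v in sorted(flag_counts.items())) or "none"
        raise ValueError(
            f"no evaluable cells among {len(cells)} (QC exclusions: {detail})"
        )
    n_pos = int((ratios[evaluable] < tau).sum())
    n_eval = int(evaluable.sum())
    return TranslocationResult(n_pos / n_eval, n_pos, n_eval)


def midpoint_tau(vehicle_ratios: Sequence[float], stress_ratios: Sequence[float]) -> float:
    """Data-driven classification threshold: the midpoint between the
    median ratios of vehicle- and stress-treated negative-control
    cells. A reproducible stand-in for a manual counting criterion."""
    v = np.asarray(vehicle_ratios, dtype=float)
    s = np.asarray(stress_ratios, dtype=float)
    v, s = v[np.isfinite(v)], s[np.isfinite(s)]
    if v.size == 0 or s.size == 0:
        raise ValueError("need evaluable cells in both the vehicle and stress arms")
    return 0.5 * (float(np.median(v)) + float(np.median(s)))


def cells_to_frame(records: Sequence[CellRecord], plate_id: str = "",
                   replicate_id: str = "", field_index: int = 1) -> pd.DataFrame:
    """Tabulate cell records; QC flags are semicolon-joined tokens."""
    return pd.DataFrame({
        "plate_id": plate_id,
        "replicate_id": replicate_id,
        "well_id": [c.well_id for c in records],
        "field": field_index,
        "cell_id": [c.cell_id for c in records],
        "nuc_mean": [c.nuc_mean for c in records],
        "ring_mean": [c.ring_mean for c in records],
        "nc_ratio": [c.nc_ratio for c in records],
        "nuc_area": [c.nuc_area for c in records],
        "ring_area": [c.ring_area for c in records],
        "centroid_row": [c.centroid_row for c in records],
        "centroid_col": [c.centroid_col for c in records],
        "qc_flags": [";".join(c.qc_flags) for c in records],
    })


def match_to_truth(records: Sequence[CellRecord], truth: pd.DataFrame,
                   max_dist: float = 5.0) -> pd.DataFrame:
    """Pair measured cells with ground-truth cells by nearest centroid.

    Used by recovery tests: segmentation labels cells in scan order,
    the generator in placement order, so identity must be re-derived
    geometrically. Unmatched cells are dropped.
    """
    if truth.empty or not records:
        return pd.DataFrame()
    centers = truth[["center_row", "center_col"]].to_numpy(float)
    rows = []
    for rec in records:
        d2 = (centers[:, 0] - rec.centroid_row) ** 2 + (centers[:, 1] - rec.centroid_col) ** 2
        j = int(np.argmin(d2))
        if d2[j] <= max_dist ** 2:
            rows.append({
                "cell_id": rec.cell_id,
                "nc_ratio": rec.nc_ratio,
                "nuc_mean": rec.nuc_mean,
                "ring_mean": rec.ring_mean,
                "expected_ratio": float(truth.iloc[j]["expected_ratio"]),
                "f_cyt": float(truth.iloc[j]["f_cyt"]),
                "clipped": bool(truth.iloc[j]["clipped"]),
            })
    return pd.DataFrame(rows)
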