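"""Well aggregation, assay quality, hit calling and replicate concordance.

Cells are aggregated to one ratio per well; assay robustness is the
standard Z'-factor computed between stress- and vehicle-treated
negative-control wells; screen hits are stress-treated library wells
whose ratio exceeds the screen-wide mean plus ``k`` standard
deviations (k = 3 by default, strict inequality), pooled across plates
within a replicate; final hits must recur in at least 2 of 3
replicates. A death-siRNA transfection check and a between-replicate
Pearson correlation complete the plate-level QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import CellRecord

log = logging.getLogger(__name__)

EXCLUDE_TOO_FEW = "too_few_cells"
EXCLUDE_NO_IMAGE = "no_image"
EXCLUDE_CONTROL = "control"

WELL_COLUMNS = [
    "plate_id", "replicate_id", "well_id", "gene_id", "role", "treatment",
    "n_cells_evaluable", "well_ratio", "excluded", "exclude_reason",
]


@dataclass
class WellSummary:
    """Aggregate ratio for one well, or an exclusion with its reason."""

    plate_id: str = ""
    replicate_id: str = ""
    well_id: str = ""
    gene_id: str = ""
    role: str = "library"
    treatment: str = "stress"
    n_cells_evaluable: int = 0
    well_ratio: float = float("nan")
    excluded: bool = False
    exclude_reason: str = ""


@dataclass
class ScreenStats:
    """Screen-wide location/scale of the stress-treated library wells
    and the derived hit threshold for one replicate."""

    replicate_id: str
    mean_m: float
    sd_sigma: float
    k_sigma: float
    hit_threshold: float
    n_wells: int
    zprime_per_plate: dict[str, float] = field(default_factory=dict)


def summarize_well(
    cells: Sequence[CellRecord],
    min_cells: int = 20,
    aggregator: str = "mean",
    **well_meta: str,
) -> WellSummary:
    """Aggregate evaluable per-cell ratios to one well value.

    Wells with fewer than ``min_cells`` evaluable cells are excluded
    with reason ``too_few_cells``. ``aggregator`` is ``mean`` (default)
    or ``median``.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    ratios = np.array([c.nc_ratio for c in cells], dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    summary = WellSummary(n_cells_evaluable=int(ratios.size), **well_meta)
    if ratios.size < min_cells:
        summary.excluded = True
        summary.exclude_reason = EXCLUDE_TOO_FEW
    else:
        summary.well_ratio = float(np.mean(ratios) if aggregator == "mean"
                                   else np.median(ratios))
    return summary


def compute_zprime(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor: 1 - 3(SD_pos + SD_neg) / |mean_pos - mean_neg|.

    Sample standard deviations (n-1). Z' <= 1 always; equal arm means
    (zero assay window) and arms with fewer than two values are errors.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each Z' arm needs at least 2 well values")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        raise ValueError("zero assay window: control arm means are equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window)


def call_hits(
    wells: pd.DataFrame,
    k_sigma: float = 3.0,
    min_wells: int = 10,
    low_side: bool = False,
    replicate_id: str | None = None,
) -> tuple[ScreenStats, pd.DataFrame]:
    """Call hits at mean + k*sigma over one replicate's library wells.

    The screen mean ``m`` and standard deviation ``sigma`` are computed
    over all evaluable stress-treated library wells pooled across
    plates; vehicle-treated and control wells never enter them. A well
    is a hit iff its ratio strictly exceeds ``m + k*sigma`` (a
    knockdown that blocked cytoplasmic accumulation, leaving the
    protein nuclear). ``low_side`` additionally calls ratios strictly
    below ``m - k*sigma``. Degenerate sigma = 0 yields zero hits with a
    warning. Returns the stats and a copy of ``wells`` with a boolean
    ``hit`` column (False for non-library/excluded rows).
    """
    df = wells.copy()
    if replicate_id is None:
        reps = df["replicate_id"].unique()
        if len(reps) != 1:
            raise ValueError("wells span multiple replicates; pass replicate_id")
        replicate_id = str(reps[0])
    else:
        df = df[df["replicate_id"] == replicate_id].copy()
    eligible = (
        (df["role"] == "library")
        & (df["treatment"] == "stress")
        & (~df["excluded"].astype(bool))
        & np.isfinite(df["well_ratio"].astype(float))
    )
    values = df.loc[eligible, "well_ratio"].astype(float)
    if len(values) < min_wells:
        raise ValueError(
            f"need >= {min_wells} evaluable stress-treated library wells, got {len(values)}"
        )
    m = float(values.mean())
    sigma = float(values.std(ddof=1))
    threshold = m + k_sigma * sigma
    df["hit"] = False
    if sigma == 0.0:
        warnings.warn("degenerate screen: sigma = 0, no hits called", stacklevel=2)
    else:
        above = eligible & (df["well_ratio"] > threshold)
        df.loc[above, "hit"] = True
        if low_side:
            below = eligible & (df["well_ratio"] < m - k_sigma * sigma)
            df.loc[below, "hit"] = True
    stats = ScreenStats(
        replicate_id=replicate_id,
        mean_m=m,
        sd_sigma=sigma,
        k_sigma=k_sigma,
        hit_threshold=threshold,
        n_wells=int(len(values)),
    )
    return stats, df


def replicate_concordance(hit_tables: pd.DataFrame, min_reps: int = 2) -> pd.DataFrame:
    """Combine per-replicate hit flags into final per-gene calls.

    ``hit_tables`` is a long table with columns replicate_id, gene_id,
    well_ratio, hit (the concatenated outputs of :func:`call_hits`,
    library rows). A gene missing from a replicate (excluded well)
    counts that replicate as a non-hit. ``final_hit`` requires a hit in
    at least ``min_reps`` replicates.
    """
    df = hit_tables[hit_tables["role"] == "library"] if "role" in hit_tables else hit_tables
    reps = sorted(df["replicate_id"].unique())
    ratio = df.pivot_table(index="gene_id", columns="replicate_id",
                           values="well_ratio", aggfunc="first")
    hit = df.pivot_table(index="gene_id", columns="replicate_id",
                         values="hit", aggfunc="first")
    hit = hit.reindex(columns=reps).astype("boolean").fillna(False).astype(bool)
    ratio = ratio.reindex(columns=reps)
    out = pd.DataFrame(index=hit.index)
    for rep in reps:
        out[f"ratio_{rep}"] = ratio[rep]
        out[f"hit_{rep}"] = hit[rep]
    out["n_replicates_hit"] = hit.sum(axis=1).astype(int)
    out["final_hit"] = out["n_replicates_hit"] >= min_reps
    return out.reset_index().rename(columns={"index": "gene_id"})


def replicate_correlation(wells_a: pd.DataFrame, wells_b: pd.DataFrame
                          ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of well ratios between two replicates over
    the genes evaluable in both; returns (r, paired scatter data)."""
    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        sel = df
        if "role" in df:
            sel = df[(df["role"] == "library") & (df["treatment"] == "stress")]
        if "excluded" in sel:
            sel = sel[~sel["excluded"].astype(bool)]
        sel = sel[np.isfinite(sel["well_ratio"].astype(float))]
        return sel[["gene_id", "well_ratio"]]

    paired = _clean(wells_a).merge(_clean(wells_b), on="gene_id",
                                   suffixes=("_a", "_b"))
    if len(paired) < 3:
        raise ValueError(f"need >= 3 genes evaluable in both replicates, got {len(paired)}")
    a = paired["well_ratio_a"].to_numpy(float)
    b = paired["well_ratio_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: constant well-ratio vector")
    r = float(sps.pearsonr(a, b).statistic)
    return r, paired


@dataclass(frozen=True)
class TransfectionQC:
    """Plate transfection efficiency inferred from death-siRNA killing."""

    efficiency: float
    flagged: bool


def transfection_qc(
    death_well_counts: Sequence[float],
    neg_ctrl_counts: Sequence[float],
    efficiency_floor: float = 0.5,
) -> TransfectionQC:
    """Transfection efficiency = 1 - mean(death counts)/mean(control
    counts), clamped to [0, 1]; a universally lethal siRNA should empty
    its wells when transfection worked. Plates below
    ``efficiency_floor`` are flagged."""
    death = np.asarray(death_well_counts, dtype=float)
    neg = np.asarray(neg_ctrl_counts, dtype=float)
    if death.size == 0 or neg.size == 0:
        raise ValueError("need cell counts for both death and negative-control wells")
    if neg.mean() == 0:
        raise ValueError("zero negative-control cell count: cannot assess transfection")
    eff = float(np.clip(1.0 - death.mean() / neg.mean(), 0.0, 1.0))
    return TransfectionQC(efficiency=eff, flagged=eff < efficiency_floor)


# ---------------------------------------------------------------------------
# Optional figure-style plots
# ---------------------------------------------------------------------------

def plot_screen_distribution(wells: pd.DataFrame, stats: ScreenStats, path) -> None:
    """Strip plot of one replicate's well ratios with the screen mean
    (solid) and mean + k*sigma (dotted) lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lib = wells[(wells["role"] == "library") & (wells["treatment"] == "stress")
                & ~wells["excluded"].astype(bool)]
    veh = wells[(wells["treatment"] == "vehicle") & ~wells["excluded"].astype(bool)]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(lib))
    ax.scatter(x, lib["well_ratio"], s=8, c="tab:blue", label="siRNA pools")
    if len(veh):
        ax.scatter(len(lib) + np.arange(len(veh)), veh["well_ratio"], s=8,
                   c="tab:gray", label="vehicle controls")
    ax.axhline(stats.mean_m, color="red", lw=1, label="mean")
    ax.axhline(stats.hit_threshold, color="black", ls=":", lw=1,
               label=f"mean + {stats.k_sigma:g}σ")
    ax.set_xlabel("well")
    ax.set_ylabel("nuclear/cytoplasmic ratio")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_replicate_correlation(paired: pd.DataFrame, r: float, path) -> None:
    """Scatter of per-gene well ratios between two replicates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(paired["well_ratio_a"], paired["well_ratio_b"], s=8)
    ax.set_xlabel("replicate A ratio")
    ax.set_ylabel("replicate B ratio")
    ax.set_title(f"Pearson r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
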