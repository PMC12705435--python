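"""Fixed-radius proximity analysis of imaged cell tables.

Cells from multiplexed-immunofluorescence tissue-microarray cores carry
coordinates (µm), a cell type, core/patient membership, an age group and a
tumor/stroma region label.  After region-consistency and core-QC filtering,
the per-core statistic is the fraction of query cells with at least one
reference cell within a fixed radius (30 µm by default, inclusive);
per-patient medians feed a Wilcoxon rank-sum comparison of age groups with
BH correction across the comparisons in a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import bh_adjust, wilcoxon_rank_sum

CELL_COLUMNS = ["x", "y", "cell_type", "core_id", "patient_id", "age_group", "region"]
DEFAULT_STROMAL_CLASSES = ("iCAF", "myCAF", "EC")
DEFAULT_TUMOR_CLASSES = ("tumor",)


def region_consistency_filter(
    cells: pd.DataFrame,
    stromal_classes=DEFAULT_STROMAL_CLASSES,
    tumor_classes=DEFAULT_TUMOR_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop likely misclassified cells: stromal classes inside tumor regions and
    tumor classes inside stromal regions.  Unknown regions pass through."""
    stromal_in_tumor = cells["cell_type"].isin(stromal_classes) & (cells["region"] == "tumor")
    tumor_in_stroma = cells["cell_type"].isin(tumor_classes) & (cells["region"] == "stroma")
    removed = cells[stromal_in_tumor | tumor_in_stroma].copy()
    removed["reason"] = np.where(
        stromal_in_tumor[stromal_in_tumor | tumor_in_stroma],
        "stromal class in tumor region",
        "tumor class in stromal region",
    )
    return cells[~(stromal_in_tumor | tumor_in_stroma)].copy(), removed


def qc_filter_cores(cells: pd.DataFrame, qc: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Keep cores with stromal fraction in [0.10, 0.90] (boundaries retained).

    Every core present in the cell table must have a QC row.
    """
    qc = qc.set_index("core_id") if "core_id" in qc.columns else qc
    cores = cells["core_id"].unique()
    missing = [c for c in cores if c not in qc.index]
    if missing:
        raise ValueError(f"cores without QC rows: {missing}")
    sf = qc["stromal_fraction"]
    passing = [c for c in cores if 0.10 <= sf.loc[c] <= 0.90]
    return cells[cells["core_id"].isin(passing)].copy(), passing


def fraction_within_radius(
    core_cells: pd.DataFrame,
    query_type: str,
    reference_type: str,
    radius: float = 30.0,
) -> float:
    """Fraction of query cells with >=1 reference cell within ``radius`` (inclusive).

    Self matches are excluded by cell identity (the frame index), so two
    distinct coincident cells still count as neighbors.  Returns NaN when
    the core has no query cells, 0.0 when it has no reference cells.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    q = core_cells[core_cells["cell_type"] == query_type]
    r = core_cells[core_cells["cell_type"] == reference_type]
    if len(q) == 0:
        return np.nan
    if len(r) == 0:
        return 0.0
    tree = cKDTree(r[["x", "y"]].to_numpy(dtype=float))
    neighbors = tree.query_ball_point(q[["x", "y"]].to_numpy(dtype=float), r=radius)
    ref_ids = r.index.to_numpy()
    hits = 0
    for qid, nbrs in zip(q.index, neighbors):
        if any(ref_ids[j] != qid for j in nbrs):
            hits += 1
    return hits / len(q)


def patient_summary(core_fractions: pd.DataFrame) -> pd.DataFrame:
    """Median per-core fraction per patient (computable cores only)."""
    usable = core_fractions.dropna(subset=["fraction"])
    return (
        usable.groupby(["patient_id", "age_group"], observed=True)["fraction"]
        .median()
        .reset_index(name="median_fraction")
    )


@dataclass
class ProximityResult:
    core_fractions: pd.DataFrame
    patient_medians: pd.DataFrame
    comparisons: pd.DataFrame
    removed_cells: pd.DataFrame
    passing_cores: list


def compare_groups(medians_by_comparison: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Wilcoxon rank-sum of old vs young patient medians per comparison, BH across
    the comparisons tested in this run.  Comparisons with <2 patients per
    group are flagged untested."""
    rows = []
    for label, medians in medians_by_comparison.items():
        young = medians.loc[medians["age_group"] == "young", "median_fraction"].to_numpy()
        old = medians.loc[medians["age_group"] == "old", "median_fraction"].to_numpy()
        if len(young) < 2 or len(old) < 2:
            rows.append(dict(comparison=label, n_young=len(young), n_old=len(old),
                             w=np.nan, p=np.nan, median_young=np.nan,
                             median_old=np.nan, tested=False))
            continue
        res = wilcoxon_rank_sum(old, young)
        rows.append(dict(comparison=label, n_young=len(young), n_old=len(old),
                         w=res.w, p=res.p,
                         median_young=float(np.median(young)),
                         median_old=float(np.median(old)), tested=True))
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    mask = out["tested"].astype(bool) if len(out) else np.array([], dtype=bool)
    if len(out) and mask.any():
        out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def proximity_analysis(
    cells: pd.DataFrame,
    qc: pd.DataFrame,
    pairs: list[tuple[str, str]],
    radius: float = 30.0,
    stromal_classes=DEFAULT_STROMAL_CLASSES,
    tumor_classes=DEFAULT_TUMOR_CLASSES,
) -> ProximityResult:
    """Full chain: region filter -> core QC -> per-core fractions -> patient
    medians -> age-group comparison per (query, reference) pair."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns {missing}")
    filtered, removed = region_consistency_filter(cells, stromal_classes, tumor_classes)
    filtered, passing = qc_filter_cores(filtered, qc)
    frac_rows = []
    for (core, patient, age_group), core_cells in filtered.groupby(
        ["core_id", "patient_id", "age_group"], observed=True
    ):
        for query_type, ref_type in pairs:
            frac_rows.append(
                dict(core_id=core, patient_id=patient, age_group=age_group,
                     query_type=query_type, reference_type=ref_type,
                     fraction=fraction_within_radius(core_cells, query_type, ref_type, radius))
            )
    core_fractions = pd.DataFrame(
        frac_rows,
        columns=["core_id", "patient_id", "age_group", "query_type",
                 "reference_type", "fraction"],
    )
    medians_all = []
    by_comparison = {}
    for (qt, rt), grp in core_fractions.groupby(
        ["query_type", "reference_type"], observed=True
    ):
        med = patient_summary(grp)
        med["query_type"], med["reference_type"] = qt, rt
        medians_all.append(med)
        by_comparison[f"{qt}:{rt}"] = med
    patient_medians = (
        pd.concat(medians_all, ignore_index=True)
        if medians_all
        else pd.DataFrame(columns=["patient_id", "age_group", "median_fraction"])
    )
    comparisons = compare_groups(by_comparison)
    return ProximityResult(core_fractions, patient_medians, comparisons, removed, passing)
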