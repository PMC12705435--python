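"""Regression-based curation of cohort-stratified ligand–receptor tables.

The input schema is the downstream output of a cell–cell communication
tool: one row per (cohort, source, target, pathway, ligand–receptor pair)
with an interaction probability and a p-value.  Cell types are selected by
total signal strength against a data-derived threshold, pathways by a
univariate logistic regression of mean probabilities on age cohort, and
individual signaling nodes are classified as cohort-exclusive, -biased or
shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import LogisticFitResult, logistic_fit

RECORD_COLUMNS = ["cohort", "source", "target", "pathway", "lr_pair", "prob", "pval"]
COHORTS = ("young", "old")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"interaction table missing columns {missing}")
    bad = set(records["cohort"].unique()) - set(COHORTS)
    if bad:
        raise ValueError(f"unknown cohort labels {sorted(bad)}; expected {COHORTS}")
    if (records["prob"] < 0).any() or ~np.isfinite(records["prob"]).all():
        raise ValueError("probabilities must be finite and >= 0")
    return records


def aggregate_strengths(records: pd.DataFrame) -> pd.DataFrame:
    """Total interaction strength per (cell type, role, cohort).

    Strength sums probabilities over all partners; a homotypic record
    contributes to both the source and the target totals of its cell type.
    Absent combinations report strength 0.
    """
    records = _check_records(records)
    types = sorted(set(records["source"]) | set(records["target"]))
    rows = []
    for cohort in COHORTS:
        sub = records[records["cohort"] == cohort]
        src = sub.groupby("source", observed=True)["prob"].sum()
        tgt = sub.groupby("target", observed=True)["prob"].sum()
        for ct in types:
            rows.append(dict(cell_type=ct, role="source", cohort=cohort,
                             strength=float(src.get(ct, 0.0))))
            rows.append(dict(cell_type=ct, role="target", cohort=cohort,
                             strength=float(tgt.get(ct, 0.0))))
    return pd.DataFrame(rows)


@dataclass
class CellSelection:
    selected: list[str]
    thresholds: dict[str, float]  # per role
    strengths: pd.DataFrame
    excluded_manually: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_type", "reason"])
    )


def select_cell_types(
    strengths: pd.DataFrame,
    manual_exclusions: dict[str, str] | None = None,
) -> CellSelection:
    """Cell types whose signal strength exceeds the data-derived threshold.

    Per role, the threshold is the mean strength over cell types in the
    young cohort plus the mean in the old cohort; a type qualifies if it
    strictly exceeds the role threshold in either cohort for either role.
    Manual exclusions are applied afterwards with recorded reasons.
    """
    for cohort in COHORTS:
        if cohort not in set(strengths["cohort"]):
            raise ValueError(f"both cohorts required; missing {cohort!r}")
    thresholds = {}
    qualifying: set[str] = set()
    for role in ("source", "target"):
        sub = strengths[strengths["role"] == role]
        t = sum(
            sub.loc[sub["cohort"] == cohort, "strength"].mean() for cohort in COHORTS
        )
        thresholds[role] = float(t)
        over = sub[sub["strength"] > t]
        qualifying.update(over["cell_type"].tolist())
    manual_exclusions = manual_exclusions or {}
    dropped = [
        dict(cell_type=ct, reason=reason)
        for ct, reason in manual_exclusions.items()
        if ct in qualifying
    ]
    selected = sorted(qualifying - set(manual_exclusions))
    return CellSelection(
        selected=selected,
        thresholds=thresholds,
        strengths=strengths,
        excluded_manually=pd.DataFrame(dropped, columns=["cell_type", "reason"]),
    )


def pathway_mean_probabilities(
    records: pd.DataFrame, selected_types: list[str]
) -> pd.DataFrame:
    """Mean probability over ligand–receptor pairs per (pathway, source, target, cohort),
    restricted to source–target combinations among the selected cell types.
    Combinations without rows are absent, not zero."""
    records = _check_records(records)
    keep = records["source"].isin(selected_types) & records["target"].isin(selected_types)
    sub = records[keep]
    return (
        sub.groupby(["pathway", "source", "target", "cohort"], observed=True)["prob"]
        .mean()
        .reset_index(name="mean_prob")
    )


@dataclass
class PathwayRegression:
    pathway: str
    coef: float
    se: float
    p: float
    frequency: int
    testable: bool
    selected: bool = False


def pathway_regressions(mean_probs: pd.DataFrame) -> list[PathwayRegression]:
    """Per pathway: logistic regression of cohort (old=1) on mean probability.

    Observations are the observed (source, target, cohort) mean-probability
    rows of the pathway; frequency counts the unique source–target
    combinations in which the pathway appears, regardless of cohort.
    """
    out = []
    for pathway, grp in mean_probs.groupby("pathway", observed=True):
        freq = grp[["source", "target"]].drop_duplicates().shape[0]
        x = grp["mean_prob"].to_numpy(dtype=float)
        y = (grp["cohort"] == "old").to_numpy(dtype=float)
        try:
            fit = logistic_fit(x, y)
        except ValueError:
            fit = LogisticFitResult(np.nan, np.nan, np.nan, np.nan, False, False)
        out.append(
            PathwayRegression(
                pathway=str(pathway), coef=fit.coef, se=fit.se, p=fit.p,
                frequency=freq, testable=fit.testable,
            )
        )
    return out


def prioritize_pathways(
    regressions: list[PathwayRegression],
    p_thresh: float = 0.05,
    min_freq: int = 15,
) -> pd.DataFrame:
    """Select pathways with Wald p below threshold appearing in enough combos."""
    rows = []
    for reg in regressions:
        reg.selected = bool(
            reg.testable and reg.p < p_thresh and reg.frequency >= min_freq
        )
        rows.append(
            dict(pathway=reg.pathway, coef=reg.coef, se=reg.se, p=reg.p,
                 frequency=reg.frequency, testable=reg.testable, selected=reg.selected)
        )
    return pd.DataFrame(
        rows, columns=["pathway", "coef", "se", "p", "frequency", "testable", "selected"]
    )


def classify_nodes(
    records: pd.DataFrame,
    selected_pathways: list[str],
    p_thresh: float = 0.01,
    fold: float = 1.2,
) -> pd.DataFrame:
    """Classify each (ligand–receptor pair, source, target) node by cohort bias.

    A node is exclusive to a cohort when its p-value clears p_thresh in that
    cohort only; biased when it clears in both and the probability fold
    difference (larger/smaller) reaches ``fold`` toward one cohort; shared
    when it clears in both with a smaller fold difference.  Nodes active in
    neither cohort are omitted.
    """
    records = _check_records(records)
    sub = records[records["pathway"].isin(selected_pathways)]
    rows = []
    for (pathway, lr, src, tgt), grp in sub.groupby(
        ["pathway", "lr_pair", "source", "target"], observed=True
    ):
        by = {c: g.iloc[0] for c, g in grp.groupby("cohort", observed=True)}
        p_y = float(by["young"]["pval"]) if "young" in by else np.nan
        p_o = float(by["old"]["pval"]) if "old" in by else np.nan
        prob_y = float(by["young"]["prob"]) if "young" in by else np.nan
        prob_o = float(by["old"]["prob"]) if "old" in by else np.nan
        sig_y = np.isfinite(p_y) and p_y < p_thresh
        sig_o = np.isfinite(p_o) and p_o < p_thresh
        if not sig_y and not sig_o:
            continue
        if np.isfinite(prob_y) and np.isfinite(prob_o) and min(prob_y, prob_o) > 0:
            fd = max(prob_y, prob_o) / min(prob_y, prob_o)
        else:
            fd = np.inf
        if sig_o and not sig_y:
            cls = "older-exclusive"
        elif sig_y and not sig_o:
            cls = "younger-exclusive"
        elif fd >= fold:
            cls = "older-biased" if prob_o > prob_y else "younger-biased"
        else:
            cls = "shared"
        rows.append(
            dict(pathway=pathway, lr_pair=lr, source=src, target=tgt,
                 prob_young=prob_y, prob_old=prob_o, p_young=p_y, p_old=p_o,
                 fold_difference=fd, classification=cls)
        )
    return pd.DataFrame(
        rows,
        columns=["pathway", "lr_pair", "source", "target", "prob_young", "prob_old",
                 "p_young", "p_old", "fold_difference", "classification"],
    )


def run_interactome(
    records: pd.DataFrame,
    manual_exclusions: dict[str, str] | None = None,
    p_thresh: float = 0.05,
    min_freq: int = 15,
    node_p_thresh: float = 0.01,
    node_fold: float = 1.2,
):
    """Full curation chain: strengths -> selection -> regressions -> node calls."""
    strengths = aggregate_strengths(records)
    selection = select_cell_types(strengths, manual_exclusions)
    mean_probs = pathway_mean_probabilities(records, selection.selected)
    pathways = prioritize_pathways(
        pathway_regressions(mean_probs), p_thresh=p_thresh, min_freq=min_freq
    )
    selected = pathways.loc[pathways["selected"], "pathway"].tolist()
    sel_records = records[
        records["source"].isin(selection.selected)
        & records["target"].isin(selection.selected)
    ]
    nodes = classify_nodes(sel_records, selected, p_thresh=node_p_thresh, fold=node_fold)
    return selection, pathways, nodes
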