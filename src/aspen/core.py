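"""The dual-arm age-program enrichment pipeline at cell-type resolution.

Arm 1 ranks each eligible cell type's per-donor pseudobulk genes by Pearson
correlation with donor age and runs permutation GSEA plus a parametric
Welch gene-set test, with BH correction per cell type and per test; a
(cell type, gene set) pair is called significant only when both adjusted
p-values clear alpha.  Arm 2 assigns every cell a binned-control signature
score per gene set and correlates the per-donor, per-cell-type mean score
with age; the correlation magnitude accompanies each enrichment row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection, lognormalize, validate_dataset
from .gsea import enrichment_score, permutation_pvalue, sample_null_es
from .stats import bh_adjust, pearson_age_correlation, welch_set_test

ZERO_COEF_TOL = 1e-15  # floating-point realization of "correlation coefficient of zero"


@dataclass
class AspenConfig:
    """Tunables for a pipeline run.

    min_donor_fraction: a cell type is analyzed only if present (>=1 cell)
    in at least this fraction of donors (exactly half qualifies).
    n_permutations sets the resolution floor of the permutation p at
    1/(n_permutations + 1).  n_bins/n_ctrl parameterize the control-gene
    bins of the signature scorer.
    """

    min_donor_fraction: float = 0.5
    n_permutations: int = 10_000
    seed: int = 0
    weight_exponent: float = 1.0
    alpha: float = 0.05
    n_bins: int = 24
    n_ctrl: int = 100
    scale_factor: float = 10_000.0
    case_fold: bool = False

    def __post_init__(self):
        if not 0 < self.min_donor_fraction <= 1:
            raise ValueError("min_donor_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


def match_members(members, universe, case_fold: bool = False) -> list[str]:
    """Gene-set members present in the universe, order preserved (verbatim match
    by default; optional case folding)."""
    if case_fold:
        lut = {}
        for g in universe:
            lut.setdefault(g.casefold(), g)
        return list(dict.fromkeys(lut[m.casefold()] for m in members if m.casefold() in lut))
    uni = set(universe)
    return [m for m in members if m in uni]


def eligible_celltypes(
    cells: pd.DataFrame,
    donors: pd.DataFrame,
    min_donor_fraction: float = 0.5,
    celltype_col: str = "celltype_minor",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Retained donors per cell type, and the exclusion ledger.

    A donor is retained for a cell type iff it contributes >=1 cell of that
    type; the cell type is kept iff retained/total >= min_donor_fraction
    (presence in exactly half the donors is retained).
    """
    donor_ids = [str(d) for d in donors.index]
    if len(donor_ids) < 2:
        raise ValueError("need at least 2 donors")
    present = (
        cells.groupby([celltype_col, "donor_id"], observed=True).size().reset_index(name="n")
    )
    kept: dict[str, list[str]] = {}
    excluded = []
    for ct in sorted(cells[celltype_col].dropna().unique()):
        have = set(str(d) for d in present.loc[present[celltype_col] == ct, "donor_id"])
        retained = [d for d in donor_ids if d in have]
        if len(retained) / len(donor_ids) >= min_donor_fraction:
            kept[ct] = retained
        else:
            excluded.append(
                dict(cell_type=ct,
                     reason=f"present in {len(retained)}/{len(donor_ids)} donors "
                            f"(< {min_donor_fraction:g})")
            )
    return kept, pd.DataFrame(excluded, columns=["cell_type", "reason"])


@dataclass
class PseudobulkMeans:
    """Mean log-normalized expression per gene (rows) per retained donor (columns)."""

    cell_type: str
    expr: pd.DataFrame
    ages: np.ndarray


def pseudobulk_means(
    dataset: ExpressionDataset,
    cell_type: str,
    retained_donors: list[str],
    celltype_col: str = "celltype_minor",
) -> PseudobulkMeans:
    """Per-donor arithmetic mean of lognorm values over the donor's cells of one type."""
    if not retained_donors:
        raise ValueError("retained donor list is empty")
    lognorm = dataset.lognorm_matrix()  # cells x genes
    obs = dataset.cells
    in_type = (obs[celltype_col] == cell_type).to_numpy()
    cols = {}
    for donor in retained_donors:
        mask = in_type & (obs["donor_id"].astype(str) == str(donor)).to_numpy()
        if not mask.any():
            raise ValueError(f"donor {donor} has no {cell_type!r} cells")
        cols[donor] = np.asarray(lognorm[mask].mean(axis=0)).ravel()
    expr = pd.DataFrame(cols, index=dataset.gene_ids)
    return PseudobulkMeans(cell_type, expr, dataset.ages_for(retained_donors))


@dataclass
class AgeCorrelationRanking:
    """Genes ordered by descending Pearson correlation of pseudobulk mean with age."""

    cell_type: str
    genes: list[str]
    stats: np.ndarray
    dropped: pd.DataFrame  # columns: gene, reason in {zero-variance, zero-coefficient}
    n_donors: int


def gene_age_correlation(pb: PseudobulkMeans) -> AgeCorrelationRanking:
    """Rank genes by correlation with donor age; drop undefined and zero coefficients.

    Ties in r break lexicographically by gene id for determinism.
    """
    ages = np.asarray(pb.ages, dtype=float)
    if ages.size < 3 or np.unique(ages).size < 3:
        raise ValueError("need >=3 retained donors with distinct ages")
    X = pb.expr.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = ages - ages.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    genes = np.asarray(pb.expr.index)
    dropped = []
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    zero_var = sx == 0
    zero_coef = ~zero_var & (np.abs(r) < ZERO_COEF_TOL)
    for g in genes[zero_var]:
        dropped.append(dict(gene=g, reason="zero-variance"))
    for g in genes[zero_coef]:
        dropped.append(dict(gene=g, reason="zero-coefficient"))
    keep = ~(zero_var | zero_coef)
    if not keep.any():
        raise ValueError("all genes dropped (no defined, nonzero correlations)")
    kept_genes, kept_r = genes[keep], r[keep]
    order = np.lexsort((kept_genes, -kept_r))
    return AgeCorrelationRanking(
        cell_type=pb.cell_type,
        genes=[str(g) for g in kept_genes[order]],
        stats=kept_r[order],
        dropped=pd.DataFrame(dropped, columns=["gene", "reason"]),
        n_donors=ages.size,
    )


@dataclass
class ModuleScoreMatrix:
    """Per-cell signature scores: set-gene mean minus binned-control mean."""

    scores: pd.DataFrame  # cells x sets; NaN column if the set matched no genes
    bins: pd.Series  # bin index per gene
    seed: int
    unmatched: dict[str, list[str]] = field(default_factory=dict)
    not_scored: list[str] = field(default_factory=list)


def module_scores(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    case_fold: bool = False,
    exclude_signature: bool = False,
) -> ModuleScoreMatrix:
    """Binned-control signature score per cell per gene set.

    Genes are ranked by dataset-wide mean lognorm expression and split into
    ``n_bins`` equal-occupancy bins (ties broken by gene order, so the
    assignment is deterministic).  Each signature gene contributes
    ``n_ctrl`` control genes sampled without replacement from its bin
    (the whole bin when it is smaller); controls are pooled (unique) and the
    score is the per-cell mean over signature genes minus the mean over
    pooled controls.  One seeded generator is shared across all sets.
    """
    lognorm = dataset.lognorm_matrix()
    genes = np.asarray(dataset.gene_ids)
    n_genes = genes.size
    if n_bins > n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds gene universe size {n_genes}")
    avg = np.asarray(lognorm.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = (np.arange(n_genes) * n_bins) // n_genes
    bin_members = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    unmatched: dict[str, list[str]] = {}
    not_scored: list[str] = []
    n_cells = lognorm.shape[0]
    for name, members in gene_sets:
        matched = match_members(members, genes, case_fold)
        missing = [m for m in members if m not in set(matched)]
        if missing:
            unmatched[name] = missing
        if not matched:
            cols[name] = np.full(n_cells, np.nan)
            not_scored.append(name)
            continue
        sig_idx = np.array([gene_pos[g] for g in matched])
        sig_set = set(sig_idx.tolist())
        ctrl: set[int] = set()
        for gi in sig_idx:
            pool = bin_members[bins[gi]]
            if exclude_signature:
                pool = pool[~np.isin(pool, sig_idx)]
            if pool.size == 0:
                continue
            take = min(n_ctrl, pool.size)
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        if exclude_signature:
            ctrl -= sig_set
        if not ctrl:
            cols[name] = np.full(n_cells, np.nan)
            not_scored.append(name)
            continue
        ctrl_idx = np.fromiter(sorted(ctrl), dtype=int)
        sig_mean = np.asarray(lognorm[:, sig_idx].mean(axis=1)).ravel()
        ctrl_mean = np.asarray(lognorm[:, ctrl_idx].mean(axis=1)).ravel()
        cols[name] = sig_mean - ctrl_mean
    scores = pd.DataFrame(cols, index=dataset.cell_barcodes)
    return ModuleScoreMatrix(
        scores=scores,
        bins=pd.Series(bins, index=genes),
        seed=seed,
        unmatched=unmatched,
        not_scored=not_scored,
    )


def score_age_correlation(
    score_matrix: ModuleScoreMatrix,
    cells: pd.DataFrame,
    donors: pd.DataFrame,
    eligible: dict[str, list[str]],
    celltype_col: str = "celltype_minor",
) -> pd.DataFrame:
    """Pearson r of per-donor mean signature score vs age, per (cell type, set)."""
    rows = []
    scores = score_matrix.scores
    for ct, retained in eligible.items():
        in_type = cells[celltype_col] == ct
        for name in scores.columns:
            means, ages = [], []
            for donor in retained:
                mask = in_type & (cells["donor_id"].astype(str) == str(donor))
                vals = scores.loc[mask.to_numpy(), name]
                if len(vals):
                    means.append(float(vals.mean()))
                    ages.append(float(donors.loc[donor, "age"]))
            res = pearson_age_correlation(means, ages) if len(means) >= 3 else None
            rows.append(
                dict(cell_type=ct, gene_set=name,
                     score_age_r=res.r if res and res.defined else np.nan,
                     score_age_p=res.p if res and res.defined else np.nan,
                     score_age_defined=bool(res and res.defined))
            )
    return pd.DataFrame(rows)


def apply_dual_gate(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Significance requires both BH-adjusted p-values (permutation and
    parametric) below alpha; direction follows the NES sign."""
    table = table.copy()
    table["significant"] = (table["padj_perm"] < alpha) & (table["padj_param"] < alpha)
    table["direction"] = np.where(
        table["nes"].isna(), "", np.where(table["nes"] > 0, "older", "younger")
    )
    return table


@dataclass
class AspenResult:
    table: pd.DataFrame
    excluded: pd.DataFrame
    config: AspenConfig


def run_aspen(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection,
    config: AspenConfig | None = None,
    celltype_col: str = "celltype_minor",
) -> AspenResult:
    """Run both arms end to end and join them into the program table."""
    config = config or AspenConfig()
    report = validate_dataset(dataset)
    if not report.ok:
        raise ValueError(f"dataset failed validation: {report.summary()}")
    if len(dataset.donors) < 3:
        raise ValueError("need >=3 donors")
    if "lognorm" not in dataset.adata.layers:
        lognormalize(dataset, scale_factor=config.scale_factor)

    eligible, excluded = eligible_celltypes(
        dataset.cells, dataset.donors, config.min_donor_fraction, celltype_col
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    score_matrix = module_scores(
        dataset, gene_sets, n_bins=config.n_bins, n_ctrl=config.n_ctrl,
        seed=int(seeds[0]) % (2**31), case_fold=config.case_fold,
    )
    arm2 = score_age_correlation(
        score_matrix, dataset.cells, dataset.donors, eligible, celltype_col
    )

    rows = []
    for i, (ct, retained) in enumerate(sorted(eligible.items())):
        pb = pseudobulk_means(dataset, ct, retained, celltype_col)
        ranking = gene_age_correlation(pb)
        rng = np.random.default_rng([int(seeds[1]) % (2**31), i])
        null_cache: dict[int, np.ndarray] = {}
        for name, members in gene_sets:
            matched = match_members(members, ranking.genes, config.case_fold)
            row = dict(cell_type=ct, gene_set=name, n_donors_used=len(retained),
                       n_members=len(matched), es=np.nan, nes=np.nan,
                       p_perm=np.nan, p_param=np.nan, leading_edge="", testable=False)
            if 0 < len(matched) < len(ranking.genes):
                res = enrichment_score(
                    ranking.genes, ranking.stats, matched, config.weight_exponent
                )
                k = res.hit_positions.size
                if k not in null_cache:
                    null_cache[k] = sample_null_es(
                        ranking.stats, k, config.n_permutations, rng,
                        config.weight_exponent,
                    )
                perm = permutation_pvalue(res.es, null_cache[k])
                hit = np.zeros(len(ranking.genes), dtype=bool)
                hit[res.hit_positions] = True
                welch = welch_set_test(ranking.stats[hit], ranking.stats[~hit])
                row.update(es=res.es, nes=perm.nes, p_perm=perm.p, p_param=welch.p,
                           leading_edge=";".join(res.leading_edge),
                           testable=perm.testable and welch.testable)
            rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["cell_type", "gene_set", "n_donors_used", "n_members", "es",
                     "nes", "p_perm", "p_param", "leading_edge", "testable",
                     "padj_perm", "padj_param"]
        )
    else:
        # BH within each cell type, separately per test, over testable sets only
        for col, adj in (("p_perm", "padj_perm"), ("p_param", "padj_param")):
            table[adj] = np.nan
            for ct in table["cell_type"].unique():
                mask = (table["cell_type"] == ct) & table[col].notna()
                if mask.any():
                    table.loc[mask, adj] = bh_adjust(table.loc[mask, col].to_numpy())
    table = apply_dual_gate(table, config.alpha)
    table = table.merge(
        arm2[["cell_type", "gene_set", "score_age_r", "score_age_p"]],
        on=["cell_type", "gene_set"], how="left",
    )
    return AspenResult(table=table, excluded=excluded, config=config)
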