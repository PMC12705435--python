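# Methods

## Model and procedure

The central question is whether a gene program (a named gene set) is
enriched or depleted as a smooth function of a continuous donor covariate
— age throughout this package — within each annotated cell type of a
multi-donor single-cell expression cohort. Two statistically distinct
arms answer it in parallel; requiring agreement between them guards
against artifacts that either arm alone is prone to (ranking arm:
leading-edge domination by a handful of genes; scoring arm: cell-count
imbalance between donors).

### Eligibility

A donor contributes to a cell type only if it has at least one cell of
that type; a cell type is analyzed only if retained donors make up at
least `min_donor_fraction` (default 0.5) of the cohort, with presence in
*exactly* half retained. Excluded cell types are reported in a ledger,
never silently dropped. At least 3 retained donors with distinct ages are
required for any correlation.

### Arm 1: correlation-ranked GSEA with a dual significance gate

Counts are log-normalized per cell, ln(1 + c/total · 10⁴). Pseudobulk is
the arithmetic mean of log-normalized values over a donor's cells of the
type. Pearson r of pseudobulk vs age is computed per gene; genes with
zero variance across donors (r undefined) or |r| < 1e−15 (the
floating-point realization of a zero coefficient) are dropped to a
ledger. The ranking sorts by descending r with ties broken
lexicographically by gene identifier — deterministic by construction,
which matters because permutation results are seeded.

The enrichment score walks the ranking: members add |r|^p / Σ_set |r|^p
(p = `weight_exponent`, default 1), non-members subtract 1/(N − N_set);
ES is the signed maximum deviation. The implementation evaluates the
running sum only at hit-adjacent positions (it is monotone between hits);
a dense N-step implementation exists independently in
`aspen.validation` and the two are held equal to 1e−12 by test. When the
largest positive and negative excursions tie in magnitude within 1e−12,
the positive one is reported — the tolerance absorbs float-accumulation
differences between code paths.

The null is gene-sampling: `n_permutations` random same-size sets
(default 10 000; the p-value resolution floor is 1/(n+1)). The p-value
conditions on the sign of the observed ES and NES divides by the mean
magnitude of same-sign null scores. A multilevel/adaptive approximation
of extreme p-values is deliberately not implemented; at desk scale the
simple null is exactly specifiable and testable.

The parametric arm is a two-sample Welch t-test of the ranking statistic,
set members vs complement, with Welch–Satterthwaite degrees of freedom.
Its exact form (set vs complement, two-sided) is a documented fixed
choice among the variants the parametric gene-set test family admits.

BH adjustment is applied within each cell type, across the gene sets
tested for that cell type, separately for the permutation and parametric
p-values. The dual gate — significant iff **both** adjusted p < α — is
the logical AND of the two decisions; direction follows the NES sign.

### Arm 2: binned-control signature scores

Genes are ranked by dataset-wide mean log-normalized expression and cut
into `n_bins` (default 24) equal-occupancy bins, ties broken by gene
order so bin assignment is deterministic. Each signature gene draws
`n_ctrl` (default 100) control genes from its bin without replacement
(the whole bin when smaller); controls are pooled uniquely and the score
is the per-cell signature mean minus control mean. One seeded generator
is shared across all sets in a run. By default control pools may include
signature genes (matching the widely used scoring command); an
`exclude_signature` flag removes them, in which case adding a constant c
to all signature genes shifts scores by exactly c (a tested invariant).
Scoring uses the log-normalized layer. Per (cell type, donor) mean scores
are correlated with age; the correlation is reported ungated — its
magnitude is descriptive (bubble size), its p-value emitted for
completeness.

## Companion analyses

**Composition.** Minor-type counts are divided by the donor's total for
the parent major type; a (donor, major) pair with zero cells contributes
no observation (the proportion is undefined on an empty denominator, not
zero). Pearson correlation with age (Spearman available via a flag), BH
within each major group.

**Interactome.** Inputs are cohort-labeled (young/old) ligand–receptor
records with probabilities and p-values, the output schema of an upstream
cell–cell communication tool — the probability model itself is out of
scope. Cell-type selection: per role (source/target), the threshold is
mean strength over cell types in the young cohort plus the mean in the
old cohort; a type qualifies by strictly exceeding the threshold in
either cohort for either role. The reading of "sum of the mean strengths
of the two cohorts" per role is a documented choice; the thresholds are
data-derived, never constants. Manual exclusions apply after selection
with recorded reasons. Per pathway, mean probability per (source, target,
cohort) over its ligand–receptor pairs (missing combinations stay absent
— imputing zeros would distort the regression); univariate logistic
regression of cohort on mean probability by IRLS (max 25 iterations,
deviance tolerance 1e−8) with a Wald z test, perfect separation flagged
not-testable rather than reported as a runaway slope. Pathways pass with
p < 0.05 and presence in ≥ 15 source–target combinations. Nodes are
classified at p < 0.01: exclusive (one cohort), biased (both cohorts,
probability fold ≥ 1.2), shared (both, fold < 1.2); records reaching
p < 0.01 in neither cohort are not predicted-active nodes and are
omitted from calls.

**Spatial.** Stromal-class cells (default iCAF, myCAF, EC) in tumor
regions and tumor-class cells in stromal regions are removed as likely
misclassifications; unknown regions pass. Cores pass QC iff stromal
fraction ∈ [0.10, 0.90] (boundaries retained; the fraction is an input —
segmentation is out of scope). The per-core statistic is the fraction of
query cells with ≥ 1 reference cell at Euclidean distance ≤ r (default
30 µm, boundary inclusive). Self-matches are excluded by cell identity,
not coordinates, so coincident distinct cells count. The KD-tree search
carries an exactness contract against an all-pairs implementation.
Patient summaries are medians over passing cores; age groups are compared
by Wilcoxon rank-sum — exact enumeration when n ≤ 12 without ties
(two-sided p doubles the smaller tail), otherwise the normal
approximation with tie and continuity corrections — with BH across the
comparisons in one invocation.

## Synthetic cohorts

`simulate_cohort` draws negative-binomial counts (shared per-gene
dispersion, default 0.5) with lognormal library-size factors (CV 0.3) and
a lognormal donor × gene random effect (sd 0.25) standing in for
biological replicate variability. Defaults emulate the desk-scale
recovery setting: 8 donors with ages uniform on 35–85, six minor cell
types in three majors (~40–60 cells per donor per type), 2000 genes, five
disjoint 50-gene sets. A planted program multiplies the mean of one set's
genes in one cell type by exp(β·z(age)); the effect enters on the
log-mean linearly so the planted pseudobulk–age relation is approximately
linear, matching the Pearson arm. β = 0.65 was calibrated once so the
planted genes' per-gene pseudobulk–age correlation averages ≈ 0.9; an
optional set-level donor noise (`set_noise_sd`, default 0) can add
gene-module co-variation, but the default keeps genes independent so the
gene-sampling permutation null is exactly calibrated. What the defaults
do **not** emulate: doublets, ambient RNA, donor-level batch structure,
or correlated gene modules — so passing recovery tests demonstrates the
statistical machinery, not robustness to those real-data pathologies
(with correlated modules a gene-sampling null is known to be optimistic).

`simulate_interactions` places seven high-activity cell types among 14
weak background types so strength-threshold selection has the
few-dominant-types structure of real communication tables; pathway
presence 0.6 over the 49 strong combinations keeps a planted pathway
above the 15-combination frequency floor by construction. A planted bias
multiplies one cohort's probabilities (factor 2 in recovery studies) and
forces that cohort's node p-values under 0.01.

`simulate_cores` draws reference cells as a homogeneous Poisson process
(intensity 4·10⁻⁴ µm⁻² on a 1 mm square core) and query cells either
uniform (null) or Gaussian-displaced from random reference parents
(attraction, σ in µm per age group). Under the null the expected fraction
within r is 1 − exp(−λπr²); the closed-form check places query cells with
a margin ≥ r from the core boundary so no edge correction is needed.
Region labels split each core at x = stromal_fraction · width, so the
region-consistency filter removes a core-dependent share of reference
cells — realistic heterogeneity that makes small patient cohorts noisy;
recovery tests use 12 patients per group (clinical TMA cohorts are
larger still).

All generators are reproducible from a single integer seed through
`numpy.random.default_rng`.

## Numerical and design choices

- Natural-log normalization (base configurable); scale factor 10⁴.
- Gene identifiers match case-sensitively between matrix and gene sets;
  a case-folding flag exists. Unmatched set members are reported, never
  silently dropped.
- Duplicate gene identifiers in a features file are disambiguated by
  occurrence suffix (ACTB, ACTB.1, …).
- Feature/barcode files are accepted with or without a header line; a
  leading line is treated as a header only when the file is one line
  longer than the matrix dimension *and* the token is a recognizable
  header word — a bare length mismatch stays an error.
- BH adjustment preserves input order and is tested against the
  brute-force step-up definition on all permutations of ≤ 6 p-values.
- Null-calibration studies spread their p-value draws over several
  independent rankings, each with a null sample several times larger than
  its share of draws; a single shared finite null would make the
  one-sample KS comparison anticonservative.
- Desk-scale study sizes (20 cohorts of ~2400 cells for expression
  recovery, 1000 p-value draws for calibration, 8 cores × 400 queries for
  the spatial null, 20 interaction tables) were chosen as the smallest
  sizes at which the Monte-Carlo tolerances in the acceptance checks are
  meaningful.

## Limitations

- The permutation null samples genes, treating them as exchangeable;
  correlated gene modules violate this and inflate significance. The
  dual gate mitigates but does not remove this.
- With few donors (the realistic regime: ~10 per subtype) the per-gene
  Pearson correlations are noisy; the ranking is informative in
  aggregate, not per gene.
- The parametric arm assumes approximate normality of the correlation
  statistic within and outside the set; with heavy-tailed rankings the
  permutation arm is the more trustworthy gate.
- The interactome module consumes upstream probabilities as given; biases
  of the upstream inference propagate untouched.
- Spatial fractions ignore cell size and shape (point approximation) and
  the fixed radius is a biological convention, not an estimated scale.
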