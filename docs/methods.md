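# Methods

This note records the models behind each stage, the defaults and why,
the numerical choices, and the known limitations. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cohort model and synthetic data

The generator emulates a nine-donor lung cohort: three COPD patients
(all old; two active smokers), three old controls (two active smokers),
three young controls (never-smokers) — 4 AS / 5 NS overall. Condition
indicators are therefore partially confounded by design: every COPD
donor is old, and smoking crosses both disease groups. That confounding
is the point; the differential-expression design must disentangle it.

Counts are negative binomial in the mean/dispersion parameterization
(variance m + m²/θ, default θ = 2), drawn as a Poisson–Gamma mixture so
per-cell means factor cleanly. Per-gene baseline means are lognormal
(median 0.8, log-sd 1.0); mitochondrial genes (default 12 of 1,200,
"MT-" prefix) get an 8× scale so the mito fraction of a typical cell
sits near 7%, comfortably inside the 30% QC bound. Library size varies
lognormally per cell (log-sd 0.3). Defaults of 1,200 genes at these
baselines give a typical cell ~550 expressed genes, so ordinary cells
clear the 301-gene QC rule; simulations that use far fewer genes must
lower `min_genes` or they will (correctly) lose most cells to QC.

Three effect kinds are planted multiplicatively on the NB mean and
recorded in a truth ledger:

* condition DEGs: one gene × cell type × condition × log2FC, applied to
  the cells of donors carrying the condition (disease = COPD donors,
  aging = old donors, smoking = active smokers);
* ligand–receptor pairs: the ligand shifted in the sender type and the
  receptor in the receiver type under the same condition;
* latent modules: u_i ~ N(0, 1) per donor scales focal genes in the
  sender and target genes in the receiver by 2^(γ·u_i), inducing the
  cross-individual pseudobulk correlation the crosstalk stage detects.

Planted genes' baselines are floored at twice the median baseline: a
study's DEGs are by construction expressed genes, and planting effects
on near-silent genes would measure detection, not recovery. When many
DEGs are planted in one direction the depth normalization itself
produces small opposite shifts in all other genes (a compositional
artifact, not an estimator error); planted sets in the bundled scenarios
are therefore balanced up/down.

QC-failing cells are created either by truncating a cell to 150
expressed genes or by inflating mitochondrial counts to roughly half the
cell's UMIs, exercising both filter boundaries.

What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects between donors, cell-type abundance shifts
(composition is balanced by construction), or donor-level random
expression effects beyond the planted modules. Passing tests therefore
demonstrate the statistics behave as specified under a clean UMI model,
not that they are robust to every artifact of real tissue data.

## QC, normalization, pseudobulk

Cells are removed when expressed genes < 301 or mito fraction > 30%;
both inequalities are strict readings of the removal rule, so boundary
cells (exactly 301 genes, exactly 30%) are retained. Normalization is
counts-per-10,000 followed by natural log1p; the scale and log choice
are config-exposed since only "normalized, log-transformed" is pinned
down by convention. Pseudobulk is the arithmetic mean of normalized
values over each (individual, cell type) group; absent combinations are
flagged, never imputed as zero. The expressed set uses strict >10%
detection, which also gives `min_fraction=0` the natural meaning
"detected at least once".

## Differential expression

One design per cell type: intercept + disease (COPD vs all controls) +
age (old vs young) + smoking (AS vs NS). Rank deficiency is detected and
reported with the collinear column names rather than silently dropped.

`pseudobulk_lm` collapses to nine donor-level means and runs vectorized
OLS; with n = 9 and p = 4 the t(5) p-values are exactly calibrated under
approximately normal pseudobulk means (means over tens of cells are).
This is the default wherever calibrated error control matters, and with
a single binary covariate it reduces exactly to the two-sample t-test
(tested against that oracle).

`cell_hurdle` fits, per gene: a logistic regression of detection on the
design and an OLS of the positive log-normalized values on the design,
both with cluster-robust (by donor) covariance; each part's Wald
statistic is referenced against t(G−1) (G = donors), converted to a
signed normal quantile, and the parts are combined by Stouffer's method.
The reported log2FC is always the all-cells OLS coefficient divided by
ln 2 — a covariate-adjusted difference of mean log-scale expression.
Note this functional is not the log2 ratio of NB means: zero-inflation
makes the two differ for strong effects, and only the direction and
rough magnitude should be compared across them.

Known limitation: with nine donors and only three carrying the disease
label, cluster-robust variance is anti-conservative (~18% rejection at
nominal 5% on null simulations) — the few-treated-clusters pathology of
sandwich estimators, not a data artifact (plain OLS on the same nulls is
exactly calibrated). `cell_hurdle` is accordingly the power-oriented
cell-level method; DEG calling in the pipeline defaults to
`pseudobulk_lm`. The alternative "individual fixed effects" mode cannot
identify donor-level contrasts (the dummies absorb them) and is kept
only with rank-guarded dummy dropping.

DEG thresholds (BH FDR < 0.05 within cell type × condition, |log2FC| ≥
0.25) are conventional defaults, config-exposed.

## Prioritization

Raw DEG counts confound perturbation with statistical power, so every
cell type is downsampled to the same cell number (the minimum across
included types by default; types under a 30-cell floor are excluded with
a warning), stratified by donor so each replicate preserves the cohort
design. DE runs per replicate and the median DEG count per condition
ranks the types; ties break deterministically by name. An optional
per-cell normalization mode (count / n_cells) covers the alternative
reading of count normalization; equal-n downsampling is the default
because it equalizes power rather than rescaling unequal power.

The separability score draws equal-size condition groups, takes the top
500 variance genes, and scores a 100-tree random forest by 3-fold
stratified cross-validated AUC. Cells identical to an opposite-class
cell are provably class-uninformative but leak labels through CV (the
twin sits in training with the other label), so such pairs are dropped
before scoring; fully duplicated input returns chance AUC with a
warning.

## Ligand–receptor connectome

Score(L, R, A→B) = (mean L in A + mean R in B)/2 on normalized values,
gated at strict >10% detection of L in A and R in B, clusters under 3
cells gated out. The null shuffles cluster labels (default 1,000
permutations); p = (1 + #{null ≥ obs})/(1 + n_perm), the pseudocount
avoiding zero p-values. An exact mode enumerates every distinct label
assignment for tiny instances and is tested for equality against an
independent brute-force enumeration. Only simple two-gene pairs are
supported (no multi-subunit complexes — a deliberate dialect
restriction), and condition tables are computed by running the test
separately on case and control cells.

Delta matrices count significant pairs per ordered (sender, receiver)
pair in each group; percent change is undefined (flagged NaN) when the
control count is zero; the network keeps edges with |change| strictly
above 10%, and per-type totals sum deltas over all pairs in which the
type appears as sender plus as receiver. Enhanced pairs are classified
ligand-up / receptor-up / both / neither from up-DEGs of the endpoint
cell types; a fourth "neither" class is needed because an enhanced pair
may owe its significance to neither endpoint being a DEG.

## Trajectory and driver enrichment

Pseudotime is the projection of cells (two clusters only) onto the axis
joining cluster centroids in PC space (default 10 PCs), min–max scaled
with the start cluster at 0. This is intentionally not principal curves:
a monotone ordering between two endpoints is all the driver analysis
consumes. Per-gene association is the F statistic of a natural cubic
spline regression on pseudotime (4 knots at quantiles; truncated-power
natural basis) against the intercept-only model; constant genes get
statistic 0, p 1. Driver sets are the top N by statistic, with the
lineage conventions N = 250 (monocyte classical→intermediate), 500
(AT2→AT1), 100 (club lineages) as defaults.

Enrichment of a DEG set among drivers is a one-sided two-sample K-S test
with the alternative "DEG statistics stochastically larger". Which two
samples enter the test admits two readings; the default compares
statistic values of DEG vs non-DEG tested genes, and a rank-based mode
(rank positions of DEGs vs non-DEGs) is provided. Both are documented;
neither is asserted as the only correct reading.

## Enrichment statistics

Fisher's exact test over an explicit background; hits outside the
background raise unless the caller explicitly permits intersection —
silent intersection hides upstream bookkeeping errors. The sample odds
ratio a·d/(b·c) is reported (not the conditional MLE); degenerate ORs
(b·c = 0) are flagged rather than continuity-corrected. The composition
test is the same machinery over cells (subtype × exposure). The
functional-overlap score reports overlap size, Jaccard, and the
hypergeometric over-representation p; ranking defaults to the p-value.

## Crosstalk correlation

Spearman ρ (average ranks on ties) between each focal gene's pseudobulk
vector in the sender and every expressed gene's pseudobulk vector in a
recipient, over the donors possessing both cell types (pairwise
dropping; fewer than 5 donors is an error — at n < 5 the rank
correlation is essentially discrete; the emulated design has 9). Donors
are pooled across exposure groups by default, with an option to
restrict. Constant vectors yield flagged NaN, a focal gene's
self-correlation is excluded from sender-side lists, and the proportion
denominator is the recipient's full expressed set. With n = 9,
P(|ρ| ≥ 0.8) under independence is ≈ 1%, which is what makes the 0.8
threshold selective; the test suite checks the n ≤ 7 tail against full
permutation enumeration and the n = 9 behavior against Monte-Carlo.

## Pipeline and reproducibility

Stages run in dependency order from one YAML config with one mandatory
seed; all stage seeds are derived offsets. Outputs are fixed-column
TSVs with a fixed float format and the manifest contains no timestamps,
so identical config + inputs give byte-identical run directories (this
is itself under test). The bundled demo config uses a six-type,
~1,000-gene cohort with balanced planted effects of every kind.

## Problem sizes

Simulated checks run at reduced but statistically adequate scale, chosen
as the smallest sizes at which the contracts under test are comfortably
identified: cohorts of 2–6 cell types with 25–140 cells per type per
donor and 300–2,000 genes; 20 simulation runs for rank-recovery rates
(threshold ≥ 95% of runs) and 50 for the ligand–receptor delta (≥ 90%);
2,000 pair-tests for permutation calibration; exhaustive enumeration
oracles at ≤ 30-cell/30-count/50-gene instances.
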