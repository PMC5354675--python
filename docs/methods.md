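# Methods

This note documents the statistical procedures implemented in
`melafidelity`, the assumptions behind the synthetic-cohort generator, the
numerical conventions chosen where several are in common use, and the known
limitations of validating the pipeline on synthetic data.

## Expression scales and harmonization

All comparative analyses run on log2(TPM + 1). RPKM tables are rescaled per
sample to TPM (columns sum to 10⁶) before the log transform. Single-cell
matrices are emitted and consumed at a ×10 TPM scale and logged as
log2(TPM/10 + 1): single-cell libraries have complexities on the order of
10⁵ transcripts, so dividing by 10 puts the pseudo-count of 1 at a
comparable detection floor.

Gene matching across datasets is exact-string on case-sensitive symbols,
and analyses run on the intersection of the gene universes; missing genes
are never imputed. Duplicate gene rows in an input table are collapsed by
the per-sample maximum, which preserves the most strongly detected isoform
row and is idempotent under re-reading.

PCA centers genes but does not scale them to unit variance: the input is
already log-scale expression, and the preceding top-variance gene filter
(default 5,000 genes) is itself variance-based, which per-gene
standardization would undo. Variance ties break lexicographically by gene
id, and the arbitrary sign of each component is fixed by making its
largest-magnitude gene loading positive.

## Synthetic cohort

The generator encodes the structural premise of the analysis: a bulk tumour
profile is a purity-weighted mixture of malignant cells with immune and
stromal contamination, while a cell line is a pure malignant population.

- A shared gene universe (default 2,000 genes) is drawn with log2 baseline
  levels N(5, 2²). A 100-gene immune block and a 40-gene stromal block are
  near-absent (1 TPM) in the malignant archetype and elevated by 2.5 log2
  units in their contaminating archetype; 50-gene MITF and AXL programs are
  elevated by 2 log2 units in their respective single-cell archetype. Each
  archetype is normalized to 10⁶ before mixing, so mixtures stay on the TPM
  scale by construction.
- Tumour TPM = p·malignant + (1−p)·[w·immune + (1−w)·stromal], with purity
  p uniform on [0.3, 0.7] per tumour. The immune share w of the
  contamination is drawn once per cohort from U(0.5, 0.9), making immune
  contamination dominate (mirroring the strong immune / weak stromal
  asymmetry of real tumour admixture) while keeping per-tumour immune
  scores a clean monotone readout of 1−p.
- Multiplicative log-normal noise (default SD 0.3 in log2 units) is applied
  before re-normalizing columns to TPM.
- The immune/stromal score tables are the mean log2(TPM+1) of the true
  immune/stromal blocks per tumour. They stand in for expression-derived
  admixture scores: the pipeline only requires scores monotone in the
  respective cell fraction, which this construction guarantees.
- SNV catalogs: each mutation in a UV-positive sample is a C>T at a
  dipyrimidine with probability 0.75 (0.30 for UV-negative samples);
  otherwise the substitution class × context cell is uniform over the 11
  non-UV cells. Records are emitted on a random strand so that downstream
  pyrimidine-strand collapse is genuinely exercised.
- Survival times are exponential with log-hazard linear in the standardized
  immune score; the slope is scaled so the above-median and below-median
  groups differ by the requested hazard ratio (default 2), with baseline
  median survival 60 months and administrative censoring at 120 months.

Every generator derives an independent random stream from the cohort seed,
so outputs are bitwise-reproducible and adding one simulation call never
perturbs another.

What the generator does **not** emulate: read counts, library size and
dropout; correlated gene modules beyond the designed blocks; realistic
copy-number segmentation; batch effects; and the long-tailed citation/usage
structure of real cell-line panels. Passing tests therefore demonstrate
that the statistics recover known structure under the stated noise model —
not that real tumour cohorts satisfy that model.

## Differential expression and the immune partition

Per-gene Welch *t* tests (unequal variances, Welch–Satterthwaite degrees of
freedom) compare cell lines to tumours on the log scale; two-sided p-values
are Benjamini–Hochberg adjusted once over the full tested universe, not
within the selected subset. Genes with zero variance in both groups and
equal means are assigned t = 0, p = 1 so constant rows cannot dominate the
ranking. The top set is the floor(5% × m) genes with smallest adjusted p;
ties break by raw p, then |t|, then gene id.

Each top gene's tumour expression is correlated (Pearson) with the immune
and stromal score; a gene is IMMUNE if r_immune > 0.4 (strict), else
STROMAL if r_stromal > 0.4, else NEITHER. When both correlations exceed the
threshold the gene is labelled IMMUNE — the analysis centers on the immune
compartment, and a deterministic precedence keeps the partition exhaustive
and exclusive. Zero-variance genes get r = 0 with a degenerate flag rather
than an undefined value.

The immune DEG value of a tumour is the sum over immune-labelled genes of
the gene's Z-score across tumours (ddof = 1; zero-SD genes contribute 0),
so values sum to zero over the cohort. Survival analysis restricts to
samples with both a score and survival information *before* taking the
median; HIGH is strictly above the median (ties go LOW); events beyond the
120-month horizon are administratively censored; Kaplan–Meier curves and
the 1-df log-rank chi-square are computed with `lifelines`.

## Fidelity ranking and transcriptional states

A line's fidelity is the mean Pearson correlation over all shared genes
against every single malignant cell (or a subset). Zero-variance pairs are
skipped, not scored 0, to avoid biasing the mean; a line with no valid pair
is an error. Order ties break by line id.

Program cell scores follow the control-gene-set construction standard in
single-cell work: expression is centered per gene across cells (relative
expression), the raw program score is the mean relative expression of the
program genes, and the control score averages, per program gene, 100 genes
drawn (seeded) from the same average-expression bin out of 25. Subtracting
the control removes cell-complexity bias. The MITF-vs-AXL ranking key is
the *difference* of the two subtracted scores: subtracted scores are
regularly zero or negative, so a literal quotient is ill-defined, and on
the additive log scale the difference is the monotone ranking surrogate.
The 400 cells with the largest/smallest keys define the MITF-top and
AXL-top reference sets (k is halved with a warning when fewer than 2k cells
exist; boundary ties break by cell id and the two sets are disjoint).

Per-line program enrichment is a set-level *t* statistic: in single-sample
mode, genes are Z-scored across samples and the statistic is the one-sample
*t* of the set genes' Z-scores against 0 (zero numerator with zero spread
is reported as a true 0; nonzero mean with zero spread is flagged
undefined). In two-group mode, set genes' log-fold-changes are compared to
the non-set background with a Welch *t*. These explicitly defined
statistics pin down the set-level enrichment procedure for reproducibility.

State assignment is density-mode clustering: a 2-D Gaussian KDE (Silverman
bandwidth) on the (MITF, AXL) enrichment pairs, mean-shift ascent of every
line to a density mode, modes merged when closer than the kernel bandwidth
(RMS of the marginal kernel SDs). The mode with the highest mean MITF−AXL
difference is the MITF cluster, the lowest the AXL cluster, and remaining
modes pool as INTERMEDIATE. With fewer than two modes (or degenerate
input), lines are labelled by the sign of MITF−AXL with a warning. The
procedure has no internal randomness; modes are registered in lexicographic
coordinate order so labels are invariant to input ordering.

## Mutation spectra and UV calls

Substitutions are collapsed onto the pyrimidine strand: purine-reference
records are reverse-complemented (ref/alt complemented, 5′/3′ neighbours
swapped and complemented), giving the six standard classes. A site is a
dipyrimidine if, after collapse, at least one flanking base is C or T — the
standard UV-context convention. Spectra report, per sample, the percentage
of that sample's SNVs in each class × context cell (rows sum to 100
exactly), and per group the mean and SEM across samples.

A sample is UV-signature positive when its fraction of C>T-at-dipyrimidine
SNVs over **all** SNVs exceeds 0.6 strictly; exactly 0.6 is negative. No
minimum SNV count is imposed beyond ≥ 1 (an empty catalog is undefined and
raises). Alteration-frequency comparisons use the exact two-sided binomial
test with the minimum-likelihood summation rule (all outcomes at most as
probable as the observed one), stated explicitly because two-sided
conventions differ.

## Tissue of origin and the genomic summary

The skin score of a sample is Σ_g expr_g · EE_g² / Σ EE² over the skin
panel: squaring the tissue-enrichment weights emphasises the most
skin-specific genes, and the normalization makes scores invariant to
rescaling all EE values. Panel genes missing from the expression universe
are dropped and the remaining weights re-normalized so scores stay
comparable. The score is linear in expression. The default call threshold
of 95 is tied to the variance-stabilised scale of the original skin panel;
on any other scale the threshold is a parameter to be chosen from data.

Hierarchical clustering uses Euclidean distances with the ward.D2
convention: dissimilarities enter un-squared and are squared inside the
Lance–Williams update, pinned explicitly because "Ward" implementations
differ.

Origin calls combine the two axes: skin-high (score ≥ threshold) flags a
candidate; skin-high AND UV-positive is the high-confidence quadrant. The
evidence combination is deliberately reported as a confidence level rather
than a single boolean, because score, UV status and clustering are
complementary lines of evidence rather than a fixed decision rule; samples
missing an input get NA fields with a warning. Copy-number events are AMP
when the ploidy-corrected value exceeds 1 and DEL below −0.75, both strict,
partitioning every value. The genomic summary joins state, UV flag, mean
correlation and per-gene mutation/CN status per line; a line absent from
the mutation table gets NA flags, since lack of profiling is not wild-type.

## Problem sizes and numerical checks

The bundled validation runs at desk scale: cohorts of 2,000 genes
(100 immune / 40 stromal / 50+50 program genes), 120 tumours, 30 cell
lines, 200 single cells, 100 SNVs per sample and 500-sample UV panels, with
1,000 replicates for log-rank calibration (n = 200) and 200 replicates for
power (n = 300, hazard ratio 2). Core statistics are verified against
independent brute-force oracles: hand-formula Welch *t* with the
Satterthwaite df, a step-up BH loop, full binomial enumeration (n ≤ 12), a
naive Lance–Williams ward.D2 agglomerator, and covariance
eigendecomposition for PCA. Column sums after TPM normalization hold to
1e-9 relative; spectrum rows sum to 100 within 1e-9; PCA agrees with its
oracle to 1e-8 up to sign.

## Limitations

- Generator truth is block-structured and noise is independent log-normal;
  recovery rates measured here are upper bounds for messier real data.
- The immune/stromal score stand-ins are derived from the true gene blocks,
  so they are noiseless relative to expression-derived admixture scores.
- Mode-seeking state clusters depend on the KDE bandwidth; with few lines
  or overlapping states the method intentionally falls back to the sign
  rule rather than inventing structure.
- The exact binomial comparison takes the tumour alteration rate as a fixed
  reference proportion rather than modelling its sampling error.
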