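# Methods

This note documents the statistical procedures, the synthetic-cohort model,
the numerical choices, and the known limits of what the test suite shows.

## Data model and preprocessing

The unit of quantification is the protein group: a set of accessions
indistinguishable by their observed peptides, one row of a MaxQuant-style
`proteinGroups` export. Intensities are linear, strictly positive LFQ values;
zero or blank on disk means "not quantified" and is held internally as a
single missing sentinel. Decoy ("reverse"), contaminant, and
only-identified-by-site rows are artifacts of the search engine and are
removed first.

The main analysis branch then requires, per protein, at least `min_valid = 2`
quantified values within at least one subject's technical replicates
("any-subject" semantics), collapses replicates to the per-subject median of
the quantified values (a subject with a single quantified replicate keeps
that value; all-missing stays missing), and keeps proteins quantified in at
least 70% of the subjects of at least one experimental group (the fraction is
compared inclusively, so 7 of 10 passes). Values are log₂-transformed and the
remaining missing cells are imputed (below). The correlation branch forks
before imputation: it filters for 70% completeness over *all* subjects and
performs **no** imputation, since pairwise-complete correlation handles the
remaining gaps honestly.

## Downshifted-Gaussian imputation

Missingness in LFQ plasma data is missing-not-at-random: low-abundance
proteins drop below the detection limit preferentially. Missing cells are
therefore drawn from a Normal whose location sits below the observed
distribution: for each scope unit, with observed mean μ and SD σ (n−1),

    missing ~ Normal(μ − shift·σ, (width·σ)²),  shift = 1.8, width = 0.3.

The scope defaults to per column (per subject), the dominant convention; a
whole-matrix option exists (`scope="global"`). A scope unit with fewer than
3 observed values is an error rather than a silent unstable fit. Draws
consume one seeded generator in column-major order over missing cells, so a
given seed reproduces the matrix bit-identically on any platform. Observed
cells are never touched.

## Differential abundance

*Moderated statistic.* `stat = d/(se + s0)` with `d` the log₂ mean
difference, `se` the pooled-variance standard error (df = nₐ+n_b−2), and
`s0 = 0.01`. At `s0 = 0` this is the ordinary Student t. Pooled variance is
the default because equality of variances holds for ~95% of proteins in this
kind of data (see the Levene calibration below); Welch is available.

*Permutation FDR.* Group labels of the pooled contrast columns are permuted:
exhaustively (each distinct relabeling once) when the count C(n, nₐ) does not
exceed `n_permutations` (default 250), otherwise by seeded uniform draws.
Candidate thresholds are the observed order statistics of |stat|;
`FDR(c)` = (mean null count at or above c) / (observed count at or above c),
capped at 1. The decision threshold is the smallest candidate with
`FDR(c) ≤ 0.05`; ties at the threshold are significant. The per-protein
`q` is the minimum of `FDR(c)` over candidates at or below the protein's own
statistic, which is nonincreasing in |stat| by construction. When no
candidate passes, the contrast reports zero significant proteins with a
warning rather than an arbitrary cutoff. A property worth knowing: with the
mean-count estimator and ~500 proteins, a pure-null cohort still yields one
(false) discovery in roughly 5–10% of runs — the estimator is slightly
anti-conservative exactly at discovery counts near 1, which matches its
behavior in the field's standard implementations.

*BH + fold-change arm.* For single-measurement five-group designs the route
is plain two-sided t-tests, Benjamini–Hochberg step-up adjustment
(via statsmodels), and the joint rule `q < 0.05 AND |log₂FC| ≥ 1`.

*ANOVA screen.* A one-way fixed-effects ANOVA across all experimental groups
(α = 0.05) guards the reported panel: a protein significant in a pairwise
contrast but flat across the full design is flagged `anova_excluded` and kept
out of the panel while remaining in the full results table.

*Fold changes.* Reported as percentages, `center(A)/center(B) − 1` on linear
intensities with the group median as center; the test statistic itself is
driven by log₂ means. Medians and means can disagree slightly on skewed
data; both are reported per protein.

*Assumption checks.* Shapiro–Wilk on each protein's pooled within-group
residuals, and Levene's test per two-group contrast. Levene is
median-centered by default (the Brown–Forsythe variant, scipy's default),
which holds its nominal 5% level at n = 10+10; the classic mean-centered
variant is available but is measurably liberal at this sample size
(~6% type-I error), which matters when quoting "fraction of proteins with
equal variances".

## Correlation map

Pearson correlation over pairwise-complete subjects for every pair of
variables (proteins + clinical), with pairs below `min_n = 10` shared
observations masked. Significance of a coefficient uses the exact t
transform `t = r·sqrt(n−2)/sqrt(1−r²)` with n−2 df. Clustering is
agglomerative with average linkage on `d = 1 − r`; variables with any
remaining masked correlation are dropped greedily (most-missing first, ties
by variable index) so the distance matrix is complete and the result is
order-independent. The *anchor cluster* is the smallest dendrogram node
whose leaves contain all anchor variables (default ALT, AST, ALP, GGT) —
this reproduces "the cluster containing the liver enzymes" without choosing
an arbitrary cut height. `correlate_against` ranks all proteins against one
clinical target with BH adjustment across proteins.

## Tissue-specificity classes

From a gene × tissue mRNA table, with `ratio = 5` ("at least 500% higher"
read as five-fold, the expression-atlas convention; a literal six-fold is a
config choice): *tissue enriched* if the target tissue is at least
`ratio`-fold above every other tissue; else *group enriched* if a group of
2–7 tissues containing the target (built greedily in descending expression)
is jointly `ratio`-fold above the rest; else *tissue enhanced* if the target
is `ratio`-fold above the all-tissue mean; else *not specific*. Classes are
mutually exclusive and exhaustive; "liver-specific" means any of the three
specific classes with liver as target. All comparisons are ratios, so the
classification is invariant to global rescaling of the table.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the instrument:

- **Design.** Default human preset: groups control-NGT 10, NAFLD-NGT 10,
  control-T2D 8, NAFLD-T2D 10, cirrhosis 10 (48 subjects), technical
  triplicates, 600 protein groups plus a few flagged artifact rows. A mouse
  preset mirrors a five-group diet/treatment design (6/6/7/8/6, single
  measurements).
- **Abundances.** Baselines log-uniform over 6 orders of linear magnitude
  (guaranteeing the stated dynamic-range span). Named proteins — planted
  effects, clinical drivers, QC panel markers — are placed in the top 1.5
  orders, as the corresponding real proteins are robustly quantified.
- **Effects.** Planted per group as `log2(1 + pct/100)`, so the pipeline's
  `A/B − 1` percent estimate recovers the planted value exactly on
  noise-free data. Defaults carry the study-scale effects
  (PIGR +186/+157/+298%, ALDOB +341%, VTN +22%, LGALS3BP +102%, AFM +58%,
  APOM −25%).
- **Noise.** Between-subject biological SD 0.35 log₂; replicate noise
  lognormal with σ chosen so the technical CV matches the 15% target
  (realized median CV ~0.12–0.15, within ±0.05 of target).
- **Missingness.** Per replicate measurement, missing with probability
  `logistic((midpoint − x)·steepness)` of its log₂ value. Each protein has
  its own detection midpoint, drawn around 21.0 with SD 1.5 log₂
  (slope 0.25): proteins differ widely in ionization efficiency, and a
  single global detection curve either starves the retained matrix of
  missing values or — if flattened — gives abundant proteins unrealistic
  whole-subject dropouts. These three values were calibrated once so the
  post-filter matrix lands in the 11% ± 3% missingness regime (measured
  mean 0.108 over 50 seeds) while top-abundance proteins stay essentially
  complete.
- **Clinical variables.** Four "liver enzymes" (ALT, AST, ALP, GGT) are
  noisy weighted sums of five designated driver proteins (PIGR, DPP4,
  ANPEP, TGFBI, APOE). Drivers share a latent hepatic factor (loading 0.35)
  and — when they carry no explicit planted effect — a disease-severity
  component (loading 0.5 on the standardized severity score 0/1/2 for
  control/NAFLD/cirrhosis), so the enzyme-plus-driver block forms a planted
  correlation cluster (block r ≈ 0.8–0.94) recoverable by `anchor_cluster`.
  Seventeen further clinical variables (BMI, age, lipids, ...) are
  independent noise on plausible scales. All correlations are affine-
  invariant, so the clinical units are cosmetic.
- **Reproducibility.** One root seed; per-stage child generators
  (baselines, subject noise, replicates, missingness, clinical, artifacts)
  so regenerating any cohort is bit-identical.

What the generator does **not** model: peptide-level identification,
match-between-runs, acquisition-order drift, protein-specific biological
variance (a single between-subject SD is used), or non-logistic missingness.
Consequently, passing recovery tests show the pipeline recovers effects of
the study's magnitude under honest MNAR missingness and technical noise —
they do not show performance on real instrument data, where between-protein
variance heterogeneity is substantial.

## Statistical power at the default conditions

With n = 10 vs 10 and between-subject SD 0.35 log₂, the standard error of a
log₂ difference is 0.157. Effects of +186% (1.52 log₂) and +341% (2.14 log₂)
are detected by the permutation-FDR route in ≥98% of runs. A +102% effect
(1.01 log₂, t ≈ 6) is borderline against the FDR thresholds that ~540
simultaneously tested proteins induce (~90% detection), and a −25% effect
(0.42 log₂, t ≈ 2.6) is undetectable at FDR 0.05 — in the real study such a
protein is detectable only because its biological variance is far below the
simulator's single default SD. Percent-change estimates are unbiased: the
median across 50 runs reproduces the planted value within a few percent,
while any single run scatters by roughly ±10% multiplicatively (sampling
noise of group medians).

## Numerical and degenerate-input choices

- Zero variance on both sides of a t-test: t = 0, p = 1 for equal means;
  p → 0 with a degeneracy warning otherwise.
- Constant rows cannot be z-scored and constant variables cannot be
  correlation targets: both are errors naming the offender.
- All file I/O is UTF-8 TSV, decimal point only, numeric output at 6
  significant digits; categorical fields round-trip exactly.
- Completeness thresholds compare with ≥ (ties pass); CV threshold counts
  compare strictly below, matching "CV below 20%" phrasing.
- QC marker-panel index: each panel protein is centered by its cohort
  median; the sample index is the median of centered values; outliers are
  one-sided above median + 3·(1.4826·MAD). The exact index construction for
  these panels is not published, so this is a documented minimal scale-free
  stand-in. HBA expands to HBA1/HBA2 at matching time; matching is
  case-insensitive.
- The problem sizes in the test suite (600-protein cohorts, 50-seed
  recovery loops, 250 permutations) are the package's chosen desk-scale
  defaults; they keep every property estimable with tight Monte-Carlo error
  while remaining cheap to rerun.

## Known limitations

- The permutation-FDR internals of the original GUI tool are unpublished;
  the SAM-style mean-count estimator here is the canonical published choice
  and can diverge from that tool near the decision boundary.
- Pairwise-complete correlation with `min_n = 10` guards against spurious
  coefficients but does not correct for the varying n across pairs in the
  clustering distance.
- No between-sample normalization or batch correction is performed; the
  pipeline trusts upstream LFQ normalization.
- The BH + fold-change arm assumes measurement independence across animals;
  no paired or covariate-adjusted designs.
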