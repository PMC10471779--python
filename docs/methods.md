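# Methods

`lfp` re-implements, as a tested and reusable pipeline, a whole-blood
transcriptomic workflow for stratifying an autoimmune cohort into
molecular subgroups, distilling a galectin-3 (Gal-3) interactome
fingerprint that tracks disease severity, and quantifying how far a
treatment reverts a disease expression signature in a preclinical
design. Because the cohorts such workflows run on are controlled-access,
the package ships a synthetic-data module that reproduces the
*statistical structure* the method assumes, with full ground truth, so
every stage can be validated end to end.

## The models and procedures

### Normalization (`exprprep`)

Counts are normalized with median-of-ratios size factors (reference =
genes observed in every sample; factors rescaled to geometric mean 1)
followed by `log2(count / factor + 1)`. This is a simplified,
exactly-specified variance-stabilizing transform: it preserves ranks,
maps zero to zero and is invertible given the factor. It is *not* the
parametric DESeq2 vst curve; the difference matters only for the
mean-variance profile at low counts, which is why feature selection for
clustering corrects for that profile explicitly (below). RNA-integrity
(RIN) values are binned into seven half-unit classes on [6.5, 10]
(left-closed bins, top bin closed) and used as batch labels for a
location-only adjustment: per gene, subtract the batch mean and restore
the grand mean. This deliberately replaces empirical-Bayes batch
correction (ComBat); it removes additive batch offsets exactly and
shrinks nothing.

Gene filters are applied sequentially and reported per rule: optional
keep-list (protein-coding emulation), removal of all-zero genes, then
removal of genes below 1 normalized unit in strictly more than 95% of
samples.

### Consensus subtyping (`subtyping`)

Three clusterings are run at a common k: (i) agglomerative hierarchical
clustering on the dissimilarity 1 − Pearson(sample, sample) with Ward
linkage, (ii) k-means (10 restarts), (iii) a Gaussian mixture. Labels of
(ii) and (iii) are aligned to (i) by optimal assignment (Hungarian
algorithm on the contingency table, zero-padded when label counts
differ), and a sample is assigned a consensus label only under
unanimity; everything else is AMBIGUOUS. The cluster number is chosen
where the three methods agree best, measured by the mean pairwise
adjusted Rand index, with one refinement: among k values whose agreement
is within 0.01 of the maximum, the *largest* k wins. The refinement is
forced by a property of unanimity: any clean partition's coarsening is
equally unanimous (merging two well-separated clusters is something all
three methods do identically), so a strict smaller-k tie-break would
always collapse to k = 2. A run whose best agreement is below 0.5 is
flagged as not supporting distinct clusters.

Feature preparation matters more than the clusterers. On log-scale NB
counts, raw variance ranking selects lowly expressed genes whose
variance is technical, and an informative-gene signal that is a small
fraction of the transcriptome sits below the Marchenko–Pastur noise
edge of the sample covariance, where no unsupervised method can see it.
The clusterer therefore (1) ranks genes by variance in excess of a
rolling-median mean-variance trend (the standard highly-variable-gene
device) and keeps the top `n_top_genes` (default 150), (2) standardizes
them, and (3) projects onto `n_pcs` principal components (default 5)
for k-means and the mixture; the correlation-distance hierarchical
method runs on the standardized gene matrix, where sample-sample
Pearson correlation is meaningful. The mixture uses full covariance
only when `n ≥ k·(d+1)` and falls back to diagonal otherwise.

Consensus labels are extended to held-out samples by a random forest
fit on the consensus-labeled training samples; a test sample's
confidence is the fraction of trees voting its winning class and it is
retained when confidence ≥ τ (default 0.6, matching a design in which
roughly half of a modest test set survives).

### Fingerprint selection and scores (`fingerprint`)

The candidate panel is the case-normalized union of two interactant
lists restricted to genes present in the dataset. Selection runs B
bootstrap replicates (default 200): per replicate, a stratified
bootstrap of samples (preserving cluster proportions), a random-forest
fit predicting the cluster label from the candidates, and a gene counts
as *chosen* when its out-of-bag permutation importance is strictly
positive. Importance is computed per tree — each tree's OOB accuracy
drop when the gene's values are permuted, averaged over trees — which
is the classical random-forest importance. The per-tree form is
essential: with a block of redundant informative genes, whole-forest
accuracy is insensitive to permuting any single one (masking), and a
100% frequency threshold would be unreachable. The panel keeps genes
with selection frequency ≥ the threshold (default 1.0, i.e. chosen in
every replicate). Candidate order is canonicalized internally so
frequencies do not depend on input ordering. A "top-q by importance"
per-replicate rule is available as a config switch.

Directions: a panel gene is +1 ("up") when its mean normalized
expression in the reference (most severe) cluster exceeds the mean over
the remaining patients, −1 otherwise; exact ties fall back to the
contrast against healthy volunteers (HV), then +1.

The per-sample scores over the up set G^up and down set G^down are

    score_up(i)   = median_{j ∈ G^up}   ( Y_ij − median_k Ctrl_kj )
    score_down(i) = median_{j ∈ G^down} ( Y_ij − median_k Ctrl_kj )

with Y the patient's normalized expression, Ctrl the HV reference and
the midpoint convention for even-sized medians (G^up = 48 is even, so
the convention is load-bearing). Scores are z-normalized against the HV
population's own score distribution (mean 0, sd 1 with the n−1
denominator); raw scores are always reported alongside.

### Differential expression and reversal (`diffex`)

Per gene, ordinary least squares of normalized expression on a
two-group indicator plus optional covariates; the group coefficient is
the log2-scale effect and its two-sided t-test (residual df) the
p-value. This replaces a moderated-t (empirical-Bayes variance
shrinkage) fit; a variance floor for tiny designs is available.
Zero-residual fits are clamped at p = 1e-300 (p = 1 for a zero effect).
P-values are Benjamini–Hochberg adjusted; effects become signed linear
fold-changes (2^effect if ≥ 1 else −2^−effect, so |FC| ≥ 1); a gene is
called UP/DOWN when q ≤ 0.05 and |FC| ≥ 1.3, both bounds inclusive.
Cross-group DE calls are partitioned by exact inclusion–exclusion
(exclusive / shared cells summing to the union).

Reversal analysis: pathology genes are the DE calls of disease vs
control; per treated arm, a pathology gene is *reversed* when its
treated-vs-disease change is significant in the opposite direction
(default rule), or — under the alternative "restored" rule — when the
treated arm is no longer distinguishable from control on that gene.
Both rules are implemented because the operational definition behind a
published "fully reversed" gene list is rarely stated.

### Associations (`assoc`) and PLS-DA (`plsda`)

Score–clinical tests follow feature arity: ≥ 3 groups Kruskal–Wallis
(tie-corrected, chi-square p), 2 groups two-sided Wilcoxon rank-sum
(exact when both groups are ≤ 20 and tie-free, else the corrected
normal approximation), continuous covariates Pearson correlation of
the score against the log10 count (scores can be negative and are not
transformed). The neutrophil-to-lymphocyte ratio is neutrophils/(B+T);
a zero lymphocyte total is recorded as missing.

PLS-DA is NIPALS on the column-centered (optionally unit-scaled)
expression matrix against centered one-hot labels, tolerance 1e-10,
≤ 500 iterations per component, rank-one deflation after each
component. The first weight vector is therefore the dominant
eigenvector of XᵀYYᵀX and score vectors are mutually orthogonal; signs
are fixed by making the largest-magnitude weight entry positive. Class
imbalance is not reweighted.

## The synthetic generators (`synthgen`)

`gen_cohort` emulates a cross-sectional cohort: 100 HV plus three
patient clusters of 86/120/43 with a severity gradient — log2 effects
1.0 (C3), 0.5 (C1), 0.0 (C2 ≈ HV) planted on a fingerprint of 48 up +
21 down genes embedded in a 248-gene candidate panel within a
10,000-gene transcriptome. Counts are negative binomial parameterized
by mean and dispersion α (var = μ + αμ², α = 0.1, a common bulk
RNA-seq scale), baseline expression log-normal (meanlog 4, sdlog 1.5),
fingerprint/candidate genes floored at 20 counts (curated panels are
reliably expressed transcripts), library sizes log-uniform on
[0.7, 1.4]. Clinical covariates are log-normal on the log10 scale with
slopes per severity unit of +0.15 (neutrophils), −0.15 (B cells),
−0.10 (T cells), sd 0.12 — so neutrophilia and lymphopenia track the
gradient and Pearson-on-log tests are well-posed. RIN is uniform on
[6.5, 10]; batch offsets are off by default and configurable.

`gen_preclinical` emulates a 5-arm design (control n=11; disease and
three treatments n=12) with 510 disease DEGs (484 up / 26 down, log2
effect 1.5) in a 10,000-gene transcriptome — the ~5% DEG fraction of a
realistic post-filter dataset, at which median-of-ratios size factors
are essentially unbiased. Each treatment arm restores the control mean
on a planted fraction of the DEGs (defaults 0.87 / 0.60 / 0.35,
one strong and two weaker treatments).

What the generators do *not* model: read-level noise, gene-gene
correlation beyond the planted blocks, isoforms, cell-type composition,
outlier samples, or any real batch structure. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, at the
stated sizes and noise levels — not that it would recover subgroups in
an arbitrary real cohort.

## Numerical choices and degenerate inputs

- Medians: midpoint for even counts throughout.
- Direction ties: HV fallback, then +1.
- Correlation distances clipped to [0, 2] and symmetrized before Ward.
- Constant features are dropped with a warning before clustering or
  scaled PLS-DA.
- All stochastic stages take one seed; per-stage/per-replicate seeds
  are derived via `SeedSequence` or a stable BLAKE2 hash of the stage
  name, so any stage can be rerun independently and full pipeline runs
  are bit-reproducible.
- Stability selection requires ≥ 2 clusters with ≥ 5 samples each; the
  pipeline drops smaller consensus clusters before selection.

## Known limitations

- The simplified vst and mean-centering batch adjustment do not
  reproduce DESeq2/ComBat numerically; conclusions that depend on
  shrinkage behavior at low counts are out of scope.
- Recovered reversal fractions run ~0.04 below the planted value by
  construction: the pathology set called at q ≤ 0.05 contains ~5% false
  discoveries that cannot be reversed, diluting the ratio.
- OLS differential expression is anti-conservative for n per group ≤ 3
  without the variance-floor option.
- The consensus-unanimity rule and the τ retention rule are one
  reasonable reading of a procedure whose reference implementation
  lives in external code; both are parameterized.
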