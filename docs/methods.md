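# Methods

## Background and model

Random monoallelic expression (MAE) is an epigenetic phenomenon in which
one of the two autosomal alleles of a gene is silenced, with the choice of
allele made randomly early in development and then maintained mitotically
within each clone. Because different clones silence different alleles,
polyclonal tissue samples show no net allelic imbalance in RNA-seq, and
direct detection requires clonal cell lines. MAE genes do, however, carry a
detectable chromatin signature in polyclonal material: simultaneous
gene-body enrichment of H3K36me3 (deposited over actively transcribed gene
bodies, reporting the expressed allele) and H3K27me3 (a Polycomb silencing
mark, reporting the silenced allele). Biallelically expressed (BAE) genes
show the active mark without the silencing mark.

chromae operationalizes this signature as a supervised classification
problem. Each gene contributes a feature vector of per-mark gene-body
enrichments transformed to within-sample quantile ranks; a classifier
trained on genes with known allelic status (from allele-specific RNA-seq in
clonal cell lines) then predicts MAE/BAE status genome-wide. In the
two-mark rank space, MAE genes occupy the joint-high-rank corner and the
classifier's job is to draw the boundary.

## Enrichment features

For gene *g* and mark *m* the raw feature is the mean coverage of the mark
track over the gene interval (gene body by default, or a TSS-centred
promoter window, ±2 kb by default):

  s(g, m) = (1 / |I_g|) · Σ_{b ∈ I_g} x_m(b)

with uncovered bases counted as 0 signal. Counting uncovered bases as zero
(rather than excluding them) makes the mean independent of how the track
happens to be blocked into intervals and treats absence of reads as
absence of signal, which is the appropriate reading of a coverage track.

Genes whose **control** (ChIP input) mean falls below a floor (default 0.1
track units) are removed: their ratios would be dominated by noise, and
the floor also guarantees a nonzero denominator at the default pseudocount
of 0. The ChIP mean is then normalized to the control,

  e(g, m) = (s(g, m) + c) / (s(g, control) + c),

with pseudocount c = 0 by default (configurable for users who disable the
control floor). In length-normalization mode the per-base mean is used
directly, since mean = total/length already is the length-normalized
quantity. No log transform is applied before ranking — ranks are invariant
to any monotone transform, so it would be a no-op.

Finally each mark column is converted to the fractional **quantile rank**
over the surviving genes: average competition rank divided by n, so ties
receive the mean of the positions they span, the maximum maps to 1, and n
untied values give exactly {1/n, …, 1}. Ranks are computed after all
filtering, so only genes that can be classified define the rank
distribution. The rank transform removes all scale and shape information
from the marginals, which is what makes models portable across samples
with different sequencing depth and ChIP efficiency.

X-linked genes (by chromosome name), imprinted genes and olfactory
receptor genes are excluded by default, so the analysis focuses on
autosomal *random* MAE rather than the better-characterized allele-biased
systems; the shipped imprinted/olfactory symbol lists are small editable
defaults and the pipeline runs with empty lists. Exclusion membership is
exact string match on gene ID or symbol — no fuzzy mapping is attempted.

## Training

Features are inner-joined with the MAE/BAE label table; MAE is the
positive class everywhere. Nine algorithm families are trained: logistic
regression with best-subset feature selection ("glm"; with two features,
best-subset over the three non-empty subsets is exact stepwise selection
and stays cheap), a support vector machine with linear and RBF kernels, a
fixed two-hidden-layer neural network, a tunable one-hidden-layer
perceptron, a random forest, k-nearest neighbours, adaptively boosted
trees, a decision tree with hyperparameters evolved by a small seeded
genetic algorithm, and a recursive-partitioning tree. All families train
and predict through one interface; the hyperparameter pools are small,
fixed, documented defaults and are not claimed to match any other
implementation's tuning grids.

Model selection within each family maximizes the mean **Cohen's kappa**
across stratified k-fold cross-validation (5 folds by default):

  κ = (p_o − p_e) / (1 − p_e),

where p_o is observed agreement and p_e the chance agreement from the
marginal products (κ ≡ 0 when p_e = 1). With MAE prevalence of 5-20%,
accuracy is a misleading objective — the constant-BAE predictor reaches
80-95% — while kappa corrects for chance agreement and so penalizes
degenerate solutions. Stratification is used because unstratified folds
can lose the minority class entirely at these prevalences. Folds are
shuffled with a per-algorithm seed derived deterministically from the
master seed (master + registry index), so a run is fully reproducible from
one integer. The winning configuration is refit on all training data, and
the summary reports CV-mean precision, recall, F1, kappa and accuracy per
model (labeled as CV means; with `--no-cv` the model is fit on the
complete training set and resubstitution values are reported with folds
recorded as 0).

Imbalance is handled solely through the kappa objective; no resampling
(SMOTE-style) and no probability calibration are applied. Among the
trained models, the one with the best F1 (harmonic mean of precision and
recall) is selected by default: precision-optimal models suit
high-confidence candidate lists, F1 suits genome-wide mapping. Exact
metric ties break lexicographically on the algorithm name and are logged.

## Prediction and evaluation

Applying a model to a new enrichment table yields one row per gene: either
a MAE/BAE call (with P(MAE) when the family natively produces class
probabilities — logistic regression, forests, boosted trees, kNN, MLPs —
and an empty score otherwise, e.g. for the SVM) or a filter reason. Genes
can be filtered by minimum length (default 1000 bp) and, when an
expression file is supplied, by minimum expression in the user's own units
(genes missing from a supplied expression map are treated as unexpressed).
Short genes are filtered because their mean enrichment is noisy and
gene-body marks are poorly defined on them. The class decision uses the
model's native 0.5 threshold; no threshold tuning is performed.

Evaluation counts a confusion matrix with MAE positive over the genes
shared between truth and calls; genes filtered at prediction time are
excluded from evaluation (and reported separately) rather than counted as
BAE calls. Ratios with zero denominators (e.g. precision when nothing is
called MAE) are reported as explicitly undefined — empty cells in the TSV
— never coerced to 0.

## Synthetic data generator

The generator emulates the pipeline's complete input bundle with the
statistical structure the method assumes, so every stage is testable with
no downloads. Genes (default 500) are placed without overlap on a
synthetic autosome "chrS", plus 5 decoy genes on "chrX" to exercise the
X-exclusion. Each gene draws a latent class (MAE with probability 0.10 by
default, inside the observed 5-20% prevalence range) and a target mean
signal per mark from one of two bivariate log-normal clusters in
log-signal space:

- BAE mean (log H3K36me3, log H3K27me3) = (1, 0): active mark present,
  silencing mark low;
- MAE mean = BAE mean + (σ·sep/√2)·(1, 1): elevated in *both* marks;
- within-class SD σ = 1 on both axes.

`separation` (default 4) is therefore the Euclidean distance between class
means in within-class-SD units: 0 makes the classes indistinguishable, 4
makes them nearly separable. Tracks are written as bedGraph text, one
value per 50 bp bin: the gene's target times multiplicative log-normal
noise (SD 0.25 on the log scale — modest bin-to-bin coverage roughness).
The control track is uniform per gene in [0.8, 1.2], positive everywhere a
gene lies, so the default control floor keeps all genes. Log-normals were
chosen because coverage is positive and right-skewed, but the downstream
quantile ranking destroys marginal shape — only the cluster geometry in
rank space matters, which is exactly the property the rank transform is
there to exploit.

A Monte Carlo **Bayes oracle** computes the optimal-classifier accuracy and
kappa of the generating mixture (10^6 draws by default): classify each
draw by maximum posterior under the known equal-covariance Gaussian
densities in log space. Because the rank transform is monotone per
coordinate, this ceiling also bounds classifiers operating in rank space,
and trained models are checked to approach but not beat it (up to the
Monte-Carlo/CV sampling tolerance, taken as 3 standard errors of a
proportion at the evaluated n).

What the generator does **not** emulate: read-level sampling noise and
mappability structure, overlapping and multi-isoform genes, peak-shaped
(rather than uniform) mark deposition, correlated biological covariates
such as gene expression level, and between-sample batch structure. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
self-consistent under its own assumptions — not that any particular
precision/recall will be attained on real ChIP-seq data, where label
noise and data quality dominate.

## Numerical choices and edge cases

- Coordinates are 0-based half-open internally; GTF's 1-based inclusive
  records are converted at the parse boundary.
- bedGraph overlap is rejected as an error (its meaning is ambiguous);
  bigWig means use exact summary statistics with uncovered bases as 0.
- Queries on zero-length intervals or absent chromosomes are errors, not
  zeros.
- The enrichment stage is deterministic: identical inputs give
  byte-identical output files (ranks are tie-deterministic, floats are
  printed with 6 decimals).
- A class smaller than the fold count is an error suggesting fewer folds.
- Model files embed a format-version string; foreign or truncated files
  are rejected with an error.

## Problem sizes

Default study conditions are 500 genes with 10% MAE prevalence and
separation 4; the Bayes oracle uses 10^6 Monte Carlo draws. The test suite
uses a 120-gene bundle for unit-level checks and the 500-gene conditions
for training-level checks. These sizes give stable metrics (CV standard
error on accuracy ≈ 0.005 at n = 500) while keeping a full end-to-end run
in seconds.

## Known limitations

- Two-feature best-subset "stepwise" selection degrades to ordinary
  stepwise only if more marks are supplied; with many marks a proper
  stepwise or penalized path would be preferable.
- The expression filter is unit-agnostic: thresholds are compared in
  whatever units the user's file carries.
- Overlapping genes are summarized independently; no overlap resolution.
- The default exclusion lists are representative, not exhaustive; users
  mapping real genomes should supply curated lists for their assembly.
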