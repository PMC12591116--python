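# Methods

## Data model

A cohort is three aligned blocks over one ordered subject list: genotypes
(subjects × SNPs, additive alternate-allele dosage 0/1/2, rsID column names),
imaging features (subjects × ROIs/IDPs, real-valued, units feature-specific),
and a diagnosis per subject in {NC, MCI, AD} (binary cohorts use {NC, AD};
the class set is always inferred from the labels, never hard-coded). After
intersecting the three sources, subjects are ordered lexicographically so the
result is independent of file ordering. Missing dosages default to per-SNP
mode imputation; drop-subject and drop-snp policies are available. Two
cohorts are harmonized by rsID string intersection only — no strand or
allele-flip reconciliation is attempted, so inputs are expected to be on a
consistent strand. VCF extraction counts alternate alleles per diploid GT
(0/0→0, 0/1→1, 1/1→2); multiallelic records are skipped with a warning and
missing or non-diploid calls are flagged missing rather than silently
dropped.

Splitting uses controlled rounding: global train/validation/test counts
follow the largest-remainder rule (ties and residuals resolved toward
training), and under stratification each class × split cell stays within one
subject of its proportional quota while the global counts remain exact. The
default protocol is 80/10/10.

## Encoders and preprocessing

Both modalities share one architecture: two linear layers, exact-erf GELU, a
third linear layer with inverted dropout, a residual connection back to the
first layer's output, and per-sample standardization of the resulting
d-vector (population standard deviation, ddof = 0). Standardization divides
by the row std directly, guarded by a fatal error for rows with std below
1e-12 and an epsilon floor of 1e-8; the additive-epsilon alternative was
rejected because it breaks exact idempotence of the standardization step.
Linear layers use the row-vector convention `x W + b` throughout. Weights
are initialized from U(−1/√fan_in, 1/√fan_in) with zero biases,
deterministically per seed.

Inputs are z-scored with training-split statistics before encoding — imaging
features and dosages alike. Standardizing dosages matters: the raw 0/1/2
coding has variance ≈ 2·maf·(1−maf) ≤ 0.5, which scale-disadvantages the
genotype pathway relative to unit-variance imaging columns, both during
contrastive training and when attributing predictions to individual SNPs.

The SNP-side input is the fused dosage + one-hot-diagnosis vector. During
training the true label occupies the one-hot block; at inference (and for
all downstream classification features) the label slots are zeroed, so
SNP-side embeddings cannot leak the diagnosis they are later asked to
predict. The alternative reading of the pairing scheme — two separate
MRI–SNP and MRI–label pair sets rather than one fused modality — is not
implemented as a trained configuration; the fused form is the one defined by
the loss over paired embeddings.

## Contrastive objective and optimization

The loss is the image-anchored InfoNCE form: similarities are plain dot
products of the already-standardized embeddings divided by the temperature
τ, and the softmax normalizer runs over the SNP-side embeddings of the whole
batch. The one-directional form is the default; a symmetric two-directional
variant is available behind `TrainConfig.symmetric`. The loss is computed
with a max-shift, is non-negative by construction, and equals 0 for B = 1
and ln B when all embeddings coincide.

Defaults: τ = 0.07 (standard contrastive-learning practice), d = 128,
dropout 0.1, Adam at learning rate 1e-3, batch size 64, 600 epochs; the last
incomplete batch of each epoch is kept. Note that with per-sample
standardized rows the dot products scale with d (row norm ≈ √d), so early
logits are large at τ = 0.07; Adam's per-parameter scaling handles this in
practice and training is stable across the study conditions used here.
Gradients are derived analytically (softmax backward, then the chain through
standardization, residual, dropout mask, GELU, and the linear layers) and
are checked against central finite differences in the test suite at relative
tolerance 1e-5.

Randomness is organized as named substreams (encoder inits, epoch shuffling,
dropout masks) fanned out from the single run seed, so any subsystem can be
re-run independently and the whole run is bit-reproducible. Divergence to a
non-finite loss aborts with the epoch index.

## Ensemble classification

Base models and their pinned settings: random forest (500 trees), RBF-kernel
SVM with Platt-scaled probabilities (3-fold internal calibration), and
gradient-boosted trees (300 rounds, depth 4, learning rate 0.1). These
counts are package choices made for reproducibility, not tuned values.
Voting weights default to validation-accuracy-proportional (normalized to
sum to 1; an internal stratified 20% carve-out is used if no validation set
is supplied) with a uniform scheme behind a flag. The hard vote is
`argmax_c Σ_k w_k 1(p_k = c)`; ties are broken by the highest weighted mean
predicted probability among the tied classes, then by declared class order,
so prediction is fully deterministic. Soft probabilities are the weighted
average of base-model probabilities, renormalized per row because some base
models emit float32 rows that sum to 1 only approximately.

Three modality configurations are supported: image embeddings only, SNP
embeddings only (label slots zeroed), and their concatenation. The SNP-only
route classifies embeddings by default; classifying raw dosages is possible
by passing the dosage matrix directly to `fit_ensemble`.

## Metrics

Binary AUC is the normalized Mann–Whitney U statistic computed from average
ranks (ties count ½), which equals trapezoidal ROC integration. Multiclass
AUC is the unweighted macro mean of one-vs-rest binary AUCs; this convention
is stated in every report because a single "AUC" for a 3-class task is
otherwise ambiguous. Cross-entropy floors probabilities at 1e-12 to stay
finite. Sensitivity and specificity are per-class one-vs-rest; ratios with
zero denominators are reported as missing, never as 0.

## Interpretation

Attributions target the composed raw-feature → class-probability function
(dosages and imaging features through both encoders and the ensemble), so
importances land on rsIDs and named ROIs. Absent features are marginalized
over a background sample (default: 100 training subjects drawn by seed). The
exact estimator enumerates all 2^f coalitions and is refused above 15
features; the sampling estimator is permutation Monte-Carlo with one
background row per permutation and reports per-feature Monte-Carlo standard
errors. Exact values satisfy efficiency, symmetry, and dummy by
construction, and the test suite asserts all three on constructed games.

The pairwise interaction index is the second-order Shapley decomposition
Σ_S |S|!(f−|S|−2)!/(f−1)! · [v(S∪{i,j}) − v(S∪{i}) − v(S∪{j}) + v(S)]; for a
two-feature product game at instance (1,1) with zero background it equals 1.
The sampled variant exploits the fact that this kernel puts equal mass
1/(f−1) on every coalition size: sizes are drawn uniformly, subsets
uniformly within size, and the plain mean of the four-coalition differences
is the estimate.

One-vs-rest attribution follows the three-class protocol (NC vs non-NC, MCI
vs non-MCI, AD vs non-AD). Genotype-stratified phenotype comparisons use
Kruskal–Wallis across dosage groups (two groups reduce to a two-sided
Mann–Whitney U), two-tailed at α = 0.05; groups with fewer than two subjects
are excluded from the test and fewer than two usable groups is fatal. Rank
tests were chosen for robustness to the non-normal, shifted mixtures that
genotype stratification produces; the test name is declared in the output.
No multiple-testing correction is applied by default (a Benjamini–Hochberg
adjustment helper is provided for screening many SNP–phenotype pairs), and
the output records that choice. Allele-string group labels
(GG/AG/AA) are rendered only when per-SNP allele metadata is supplied;
otherwise groups are labelled by dosage.

## Synthetic cohorts and study conditions

The simulator draws dosages per SNP as Binomial(2, maf) (Hardy–Weinberg),
assigns diagnoses either independently from the class prevalences or — when
liability SNPs are declared — by thresholding a genetic liability
ℓ = Σ γ_j (g_j − 2·maf_j) + ε, ε ~ N(0,1), at the empirical liability
quantiles matching the prevalences (class frequencies are preserved exactly
while cases are enriched for risk alleles; severity increases with
liability). ROI values are baseline + additive SNP effects + class shifts +
optional genotype-by-diagnosis terms + Gaussian noise. Draws are organized
in named substreams consumed column-by-column, so enlarging one block never
perturbs another. The manifest records every planted effect.

Two named study conditions are frozen in the package:

* `strong_effect_spec` — alignment and classification experiments: 600
  subjects (450 in the classification runs), 50 SNPs × 40 ROIs, six causal
  SNP→ROI pairs at β = 3 noise-SD per alt allele, the same six SNPs carrying
  liability γ = 1, atrophy-like shifts of −2 (AD) and −1 (MCI) noise-SD on
  the six causal ROIs, class mix 48/24/28% (an ADNI-like prevalence
  structure), maf 0.3, unit noise.
* `recovery_spec` — attribution experiments: 500 subjects, 20 SNPs × 15
  ROIs, three liability SNPs (γ = 2) and three shifted ROIs, *no* SNP→ROI
  pairs. Shapley values split credit between correlated features, so
  planting the diagnosis signal redundantly across modalities would make
  "every causal feature in the top-10" an ill-posed target; the recovery
  condition therefore gives each causal feature signal unique to itself.

What the simulator does not emulate: linkage disequilibrium between SNPs,
realistic inter-ROI covariance, site/scanner batch effects, and population
stratification. Passing the planted-effect tests therefore demonstrates that
the pipeline recovers signal it is pointed at under clean conditions — not
that it is robust to the confounding structure of real imaging-genetics
cohorts.

## Validation experiments and problem sizes

The validation suite (tests plus `scripts/acceptance.py`) runs, at sizes
chosen to keep a full run to a few CPU-minutes:

* closed-form loss values, a 100-instance independent forward-pass oracle,
  and finite-difference gradient checks (B ≤ 4, d ≤ 6);
* alignment on the strong-coupling cohort (200 epochs, package defaults):
  final loss well under half the first-epoch loss and top-1 cross-modal
  retrieval far above 10× chance;
* classification over five seeds at n = 450, 80 epochs, d = 64: mean test
  macro-AUC(combined) ≥ both single-modality configurations; on null cohorts
  the mean AUC is checked against a label-permutation 95% interval around
  0.5 rather than a fixed tolerance;
* exhaustive weighted-voting enumeration (all 3³ patterns × weight grids)
  and 200 random-instance brute-force AUC comparisons;
* Shapley axioms on constructed games, exact-vs-sampled agreement within 3
  Monte-Carlo SEs, and top-10 planted-feature recovery in ≥ 4/5 seeds on
  `recovery_spec` (20 explained test subjects, 50 background rows, 80
  permutations per subject);
* stratified-test calibration: type-I error over 1000 null replicates at
  n = 150 within the binomial 95% interval of 0.05, and power > 0.9 for a
  1-SD-per-allele effect at n = 300.

## Known limitations

The temperature default interacts with the embedding dimension (dot products
grow with d); very large d at very small τ may need a larger τ or smaller
learning rate. Accuracy-proportional voting weights are nearly uniform when
base models perform similarly. The exact Shapley estimator is exponential in
the feature count by design. The label-quantile liability model fixes class
counts given the draw, which slightly understates sampling variability of
prevalences relative to a fully stochastic threshold model.
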