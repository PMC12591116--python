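# snpmri

Contrastive cross-modal integration of SNP genotypes and MRI-derived brain
features for staging Alzheimer's disease, with game-theoretic interpretation
of what drives the predictions.

## The problem

Alzheimer's disease arises from an interplay between genetic risk and
structural brain change, but genotype arrays and image-derived phenotypes
(regional volumes, cortical surface areas, white-matter hyperintensity
burden) live in incommensurable feature spaces. `snpmri` learns a shared
embedding for the two modalities, classifies diagnostic stage
(NC / MCI / AD) from the embeddings, and attributes the predictions back to
named rsIDs and ROIs. It is aimed at imaging-genetics researchers who have
paired genotype / imaging / diagnosis tables (or a VCF plus an IDP table)
and want a reproducible multimodal baseline with built-in interpretability.

## The model

Each subject *t* contributes an imaging vector $I_t \in \mathbb{R}^{d_i}$
and a SNP-label vector $S_t \in \mathbb{R}^{d_s}$ (additive dosages 0/1/2
concatenated with a one-hot diagnosis block; the label slots are zeroed at
inference). Two parallel encoders map both into $\mathbb{R}^d$:

$$h^{(1)} = x W_1 + b_1,\quad h^{(2)} = h^{(1)} W_2 + b_2,\quad
h^{(3)} = \mathrm{GELU}(h^{(2)}),$$
$$h^{(4)} = \mathrm{Dropout}(h^{(3)} W_3 + b_3),\quad z = h^{(4)} + h^{(1)},
\quad e = \frac{z - \mu_z}{\sigma_z},$$

with GELU in its exact form $x\,\Phi(x)$ and $\mu_z, \sigma_z$ the per-sample
mean and standard deviation across the $d$ embedding dimensions. The
encoders are trained with an image-anchored, temperature-scaled contrastive
(InfoNCE) objective over batches of $B$ paired embeddings,

$$\mathcal{L} = \frac{1}{B}\sum_{t=1}^{B} -\log
\frac{\exp(e_{t,i} \cdot e_{t,s}/\tau)}
     {\sum_{t'=1}^{B} \exp(e_{t,i} \cdot e_{t',s}/\tau)},$$

optimized by Adam with analytically derived gradients (pure NumPy; the
gradients are verified against central finite differences in the test
suite). Downstream, a weighted-voting ensemble — random forest, RBF-kernel
SVM with Platt-calibrated probabilities, and gradient-boosted trees — is
fitted on the embeddings under three modality configurations (`mri_only`,
`snp_only`, `combined`) and predicts
$\hat y = \arg\max_c \sum_k w_k \mathbb{1}(p_k = c)$.

Interpretation operates on the composed raw-feature → class-probability
function: exact (subset-enumeration) and permutation-sampling Shapley
values, pairwise Shapley interaction indices, Pearson SNP × ROI correlation
matrices, and Kruskal–Wallis / Mann–Whitney genotype-stratified phenotype
tests. A synthetic cohort simulator (Hardy–Weinberg genotypes, additive
SNP→ROI effects, genetic-liability diagnosis, atrophy-like class shifts,
Gaussian noise) provides ground truth for planted-effect recovery.

## Worked example

```python
import snpmri as sm

spec = sm.strong_effect_spec(seed=0, n_subjects=600)   # planted effects
cohort, manifest = sm.simulate_cohort(spec)
split = sm.split_cohort(cohort, fractions=(0.8, 0.1, 0.1), seed=0)

model = sm.train_alignment(cohort, split, sm.TrainConfig(epochs=200, seed=0))
train = cohort.subset(split.indices("train"))
print(f"first-epoch loss {model.loss_history[0]:.2f} -> "
      f"final {model.loss_history[-1]:.2f}")
print(f"top-1 retrieval {sm.retrieval_accuracy(model, train, k=1):.2%}")

tr, va, te = (split.indices(s) for s in ("train", "validation", "test"))
F = sm.embed_features(model, cohort, "combined")
ens = sm.fit_ensemble(F[tr], cohort.labels[tr], seed=0,
                      X_val=F[va], y_val=cohort.labels[va])
report = sm.evaluate_predictions(
    cohort.labels[te], sm.predict_ensemble(ens, F[te]),
    sm.predict_proba_ensemble(ens, F[te]), classes=ens.classes)
print(f"test macro AUC {report.auc:.3f}, accuracy {report.accuracy:.3f}")

res = sm.genotype_stratified_test(cohort, "rs001", "ROI001")
print(f"{res.test_name}: p = {res.p_value:.2e}")
```

Output:

```
first-epoch loss 335.30 -> final 0.30
top-1 retrieval 95.21%
test macro AUC 0.843, accuracy 0.733
kruskal-wallis: p = 1.76e-84
```

The contrastive loss collapses by three orders of magnitude because the six
planted SNP→ROI effects make subjects cross-modally identifiable: 95% of
training subjects retrieve their own SNP-side embedding as the nearest
neighbour of their image embedding (chance is 0.2%). The macro one-vs-rest
AUC of 0.843 on the held-out test decile reflects both the genetic liability
and the atrophy-like class shifts planted by the simulator, and the
stratified test confirms the planted genotype effect on `ROI001`.

## Command-line pipeline

The same steps are scriptable from a YAML config:

```bash
snpmri simulate -c config.yaml   # cohort tables + ground-truth manifest
snpmri train    -c config.yaml   # checkpoint + loss curve
snpmri classify -c config.yaml   # ensemble + test-split predictions
snpmri evaluate -c config.yaml   # metrics.json + ROC tables
snpmri explain  -c config.yaml   # Shapley attributions + interaction edges
```

Every command is reproducible from (config, seed) and writes a run manifest.
Exit codes: 0 ok, 1 usage, 2 data error, 3 numerical failure.

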