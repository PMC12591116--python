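"""Model interpretation: Shapley attributions, pairwise Shapley interaction
indices, cross-modal Pearson correlations, and genotype-stratified phenotype
tests.

Attributions are computed for the composed raw-feature -> class-probability
function (SNP dosages and imaging features through both encoders and the
voting ensemble), so importances land directly on rsIDs and ROI names.
Absent features are marginalized over a background sample. Two estimators:

* exact — full subset enumeration (2^f coalitions, allowed for f <= 15), the
  classical Shapley weights phi_j = sum_S |S|!(f-|S|-1)!/f! [v(S u j) - v(S)];
* sampling — permutation Monte-Carlo: each draw picks a random feature order
  and one background row, and accumulates marginal contributions.

The pairwise interaction index is the symmetric second-order term
sum_{S not containing i,j} |S|!(f-|S|-2)!/(f-1)! *
[v(S u {i,j}) - v(S u i) - v(S u j) + v(S)]; the sampled variant exploits the
fact that this kernel is uniform over coalition sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

EXACT_FEATURE_LIMIT = 15


# ---------------------------------------------------------------------------
# Composed raw-feature prediction function
# ---------------------------------------------------------------------------

def raw_feature_predict_fn(align_model, ens_model, target_class: str,
                           modality: str = "combined"):
    """Map raw feature rows [dosages..., imaging...] to the ensemble's
    predicted probability of `target_class` (one-vs-rest)."""
    from .ensemble import predict_proba_ensemble

    if target_class not in ens_model.classes:
        raise UsageError(f"{target_class!r} not in {ens_model.classes}")
    n_snps = len(align_model.snp_ids)
    n_rois = len(align_model.roi_ids)
    col = list(ens_model.classes).index(target_class)

    def predict(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != n_snps + n_rois:
            raise UsageError(f"expected {n_snps + n_rois} raw features, "
                             f"got {X.shape[1]}")
        G, I = X[:, :n_snps], X[:, n_snps:]
        if ens_model.modality == "mri_only":
            F = align_model.encode_image(I)
        elif ens_model.modality == "snp_only":
            F = align_model.encode_snp(G, labels=None)
        else:
            F = np.hstack([align_model.encode_image(I),
                           align_model.encode_snp(G, labels=None)])
        return predict_proba_ensemble(ens_model, F)[:, col]

    return predict


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-subject per-feature Shapley values on the probability scale."""

    values: np.ndarray                 # (n_subjects, n_features)
    feature_names: list[str]
    target_class: str
    estimator: str                     # "exact" | "sampling"
    base_value: float                  # mean background prediction
    n_samples: int | None = None
    seed: int | None = None
    standard_errors: np.ndarray | None = None
    interaction_values: np.ndarray | None = None   # (f, f) mean over subjects
    background_spec: str = ""

    def global_importance(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _coalition_values(predict_fn, x: np.ndarray, background: np.ndarray):
    """v(S) for every coalition mask, marginalizing absent features over the
    background: v(S) = mean_b f(x_S, b_~S). One batched predict call."""
    f = x.size
    n_bg = background.shape[0]
    masks = np.arange(2 ** f)
    bits = (masks[:, None] >> np.arange(f)) & 1          # (2^f, f)
    rows = np.where(bits[:, None, :].astype(bool), x, background[None, :, :])
    preds = predict_fn(rows.reshape(-1, f))
    return np.asarray(preds, dtype=float).reshape(2 ** f, n_bg).mean(axis=1), bits


def _exact_shapley_one(predict_fn, x, background):
    f = x.size
    v, bits = _coalition_values(predict_fn, x, background)
    sizes = bits.sum(axis=1)
    w = np.array([math.factorial(s) * math.factorial(f - s - 1) / math.factorial(f)
                  for s in range(f)])
    phi = np.zeros(f)
    masks = np.arange(2 ** f)
    for j in range(f):
        without = masks[(bits[:, j] == 0)]
        phi[j] = np.sum(w[sizes[without]] * (v[without | (1 << j)] - v[without]))
    return phi, v, bits


def _sampling_shapley_one(predict_fn, x, background, n_samples, rng):
    f = x.size
    n_bg = background.shape[0]
    perms = np.array([rng.permutation(f) for _ in range(n_samples)])
    bg_rows = background[rng.integers(0, n_bg, size=n_samples)]
    # build the (f+1) nested coalitions per permutation
    rows = np.empty((n_samples, f + 1, f))
    rows[:, 0, :] = bg_rows
    for step in range(f):
        rows[:, step + 1, :] = rows[:, step, :]
        rows[np.arange(n_samples), step + 1, perms[:, step]] = x[perms[:, step]]
    preds = np.asarray(predict_fn(rows.reshape(-1, f)), dtype=float)
    preds = preds.reshape(n_samples, f + 1)
    marg = np.diff(preds, axis=1)                        # (n_samples, f) in perm order
    contrib = np.zeros((n_samples, f))
    contrib[np.arange(n_samples)[:, None], perms] = marg
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return phi, se


def shapley_values(predict_fn, X, background, target_class: str = "",
                   estimator: str = "sampling", n_samples: int = 200,
                   seed: int = 0, feature_names=None) -> AttributionResult:
    """Shapley attributions of `predict_fn` for each row of X.

    `predict_fn` maps an (n, f) matrix of raw feature rows to target-class
    probabilities. Exact enumeration is refused above 15 features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise DataError("background sample is empty")
    if background.shape[1] != X.shape[1]:
        raise DataError("background and instances differ in feature count")
    f = X.shape[1]
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(f)]
    if estimator not in ("exact", "sampling"):
        raise UsageError(f"unknown estimator {estimator!r}")
    if estimator == "exact" and f > EXACT_FEATURE_LIMIT:
        raise UsageError(
            f"exact enumeration over {f} features needs 2^{f} coalitions; "
            f"use estimator='sampling' above {EXACT_FEATURE_LIMIT} features")

    base_value = float(np.mean(predict_fn(background)))
    values = np.zeros((X.shape[0], f))
    ses = np.zeros((X.shape[0], f)) if estimator == "sampling" else None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA77]))
    for i, x in enumerate(X):
        if estimator == "exact":
            values[i], _, _ = _exact_shapley_one(predict_fn, x, background)
        else:
            values[i], ses[i] = _sampling_shapley_one(predict_fn, x, background,
                                                      n_samples, rng)
    return AttributionResult(
        values=values, feature_names=list(feature_names),
        target_class=target_class, estimator=estimator, base_value=base_value,
        n_samples=n_samples if estimator == "sampling" else None,
        seed=seed, standard_errors=ses,
        background_spec=f"{background.shape[0]} background rows",
    )


# ---------------------------------------------------------------------------
# Pairwise Shapley interaction index
# ---------------------------------------------------------------------------

def _exact_interaction_from_v(v, bits, f, i, j):
    masks = np.arange(2 ** f)
    sub = masks[(bits[:, i] == 0) & (bits[:, j] == 0)]
    sizes = bits[sub].sum(axis=1)
    w = np.array([math.factorial(s) * math.factorial(f - s - 2)
                  / math.factorial(f - 1) for s in range(f - 1)])
    delta = (v[sub | (1 << i) | (1 << j)] - v[sub | (1 << i)]
             - v[sub | (1 << j)] + v[sub])
    return float(np.sum(w[sizes] * delta))


def shapley_interaction(predict_fn, X, pair, background,
                        estimator: str = "exact", n_samples: int = 400,
                        seed: int = 0) -> np.ndarray:
    """Pairwise Shapley interaction index for `pair`, one value per row of X.

    Symmetric in the pair by construction. The sampled variant draws coalition
    sizes uniformly (the exact kernel puts mass 1/(f-1) on every size, total
    mass 1) and one background row per draw.
    """
    i, j = pair
    if i == j:
        raise UsageError("interaction pair must be two distinct features")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    f = X.shape[1]
    if not (0 <= i < f and 0 <= j < f):
        raise UsageError(f"pair {pair} out of range for {f} features")
    if f < 2:
        raise UsageError("interaction needs >= 2 features")

    out = np.zeros(X.shape[0])
    if estimator == "exact":
        if f > EXACT_FEATURE_LIMIT:
            raise UsageError("exact interaction limited to 15 features; "
                             "use estimator='sampling'")
        for t, x in enumerate(X):
            v, bits = _coalition_values(predict_fn, x, background)
            out[t] = _exact_interaction_from_v(v, bits, f, i, j)
        return out
    if estimator != "sampling":
        raise UsageError(f"unknown estimator {estimator!r}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB13]))
    others = np.array([k for k in range(f) if k not in (i, j)])
    for t, x in enumerate(X):
        deltas = np.empty(n_samples)
        # batch the 4 coalition evaluations per draw
        rows = np.empty((n_samples, 4, f))
        for m in range(n_samples):
            b = background[rng.integers(0, background.shape[0])]
            s = rng.integers(0, f - 1)              # coalition size, uniform
            S = rng.choice(others, size=s, replace=False) if s else np.array([], int)
            base = b.copy()
            base[S] = x[S]
            rows[m, 0] = base
            rows[m, 1] = base; rows[m, 1][i] = x[i]
            rows[m, 2] = base; rows[m, 2][j] = x[j]
            rows[m, 3] = base; rows[m, 3][i] = x[i]; rows[m, 3][j] = x[j]
        preds = np.asarray(predict_fn(rows.reshape(-1, f)), dtype=float)
        preds = preds.reshape(n_samples, 4)
        deltas = preds[:, 3] - preds[:, 1] - preds[:, 2] + preds[:, 0]
        out[t] = float(deltas.mean())
    return out


def interaction_matrix(predict_fn, X, background) -> np.ndarray:
    """Exact (f x f) interaction matrix averaged over the rows of X
    (f <= 15). Diagonal is zero; matrix is symmetric."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    f = X.shape[1]
    if f > EXACT_FEATURE_LIMIT:
        raise UsageError("exact interaction matrix limited to 15 features")
    M = np.zeros((f, f))
    for x in X:
        v, bits = _coalition_values(predict_fn, x, background)
        for i in range(f):
            for j in range(i + 1, f):
                val = _exact_interaction_from_v(v, bits, f, i, j)
                M[i, j] += val
                M[j, i] += val
    return M / X.shape[0]


# ---------------------------------------------------------------------------
# Pearson cross-modal correlation
# ---------------------------------------------------------------------------

def pearson_matrix(X_snp, X_img):
    """Pairwise Pearson r between SNP columns and imaging columns, with
    two-tailed p-values from the t distribution on n-2 df.

    Returns (R, P), both (S x R)-shaped; constant columns yield NaN entries
    with a logged warning.
    """
    A = np.atleast_2d(np.asarray(X_snp, dtype=float))
    B = np.atleast_2d(np.asarray(X_img, dtype=float))
    n = A.shape[0]
    if B.shape[0] != n:
        raise DataError("the two blocks differ in subject count")
    if n < 3:
        raise DataError("Pearson correlation needs >= 3 subjects")

    def standardized(M, what):
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        const = sd < 1e-12
        if const.any():
            logger.warning("%d constant %s column(s); correlations set to NaN",
                           int(const.sum()), what)
        sd_safe = np.where(const, 1.0, sd)
        Z = (M - mu) / sd_safe
        Z[:, const] = np.nan
        return Z

    Za = standardized(A, "SNP")
    Zb = standardized(B, "imaging")
    R = Za.T @ Zb / n
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R ** 2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    P[np.isnan(R)] = np.nan
    return R, P


# ---------------------------------------------------------------------------
# Genotype-stratified phenotype comparison
# ---------------------------------------------------------------------------

@dataclass
class StratifiedTestResult:
    """Rank-test comparison of a phenotype across genotype groups."""

    snp_id: str
    phenotype_id: str
    groups: list[dict] = field(default_factory=list)  # genotype[, diagnosis], n, median, q1, q3
    statistic: float = np.nan
    p_value: float = np.nan
    test_name: str = ""
    alpha: float = 0.05
    per_diagnosis_p: dict | None = None

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _genotype_label(dosage: int, alleles) -> str:
    if alleles is None:
        return f"dosage_{dosage}"
    ref, alt = alleles
    return {0: ref + ref, 1: alt + ref, 2: alt + alt}[dosage]


def _rank_test(samples):
    """Kruskal-Wallis across >= 3 groups; two groups reduce to a two-sided
    Mann-Whitney U."""
    if len(samples) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
        return float(stat), float(p), "mann-whitney-u (two-sided)"
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p), "kruskal-wallis"


def genotype_stratified_test(cohort: CohortTable, snp_id: str, phenotype_id: str,
                             by_diagnosis: bool = False,
                             alpha: float = 0.05) -> StratifiedTestResult:
    """Compare a phenotype's distribution across genotype groups (dosage
    0/1/2) with a rank-based test; two-tailed at the given alpha.

    Groups with fewer than 2 subjects are excluded from the test (kept in the
    summaries). With by_diagnosis, group summaries are crossed with the
    diagnosis and per-diagnosis p-values are reported in addition to the
    pooled test.
    """
    if snp_id not in cohort.snp_ids:
        raise DataError(f"unknown SNP {snp_id!r}")
    if phenotype_id not in cohort.roi_ids:
        raise DataError(f"unknown phenotype {phenotype_id!r}")
    g = cohort.genotypes[:, cohort.snp_ids.index(snp_id)]
    y = cohort.imaging[:, cohort.roi_ids.index(phenotype_id)]
    alleles = cohort.alleles.get(snp_id)

    dosages = sorted(int(d) for d in np.unique(g))
    samples, sizes = [], {}
    groups = []
    for d in dosages:
        mask = g == d
        sizes[d] = int(mask.sum())
        vals = y[mask]
        if by_diagnosis:
            for cls in cohort.classes:
                sub = vals[cohort.labels[mask] == cls]
                if sub.size:
                    q1, med, q3 = np.percentile(sub, [25, 50, 75])
                    groups.append({"genotype": _genotype_label(d, alleles),
                                   "diagnosis": cls, "n": int(sub.size),
                                   "median": float(med), "q1": float(q1),
                                   "q3": float(q3)})
        else:
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                groups.append({"genotype": _genotype_label(d, alleles),
                               "n": int(vals.size), "median": float(med),
                               "q1": float(q1), "q3": float(q3)})
        if sizes[d] >= 2:
            samples.append(vals)
    if len(samples) < 2:
        raise DataError(
            f"need >= 2 genotype groups with >= 2 subjects each for {snp_id}; "
            f"group sizes were {sizes}")

    stat, p, name = _rank_test(samples)
    per_diag = None
    if by_diagnosis:
        per_diag = {}
        for cls in cohort.classes:
            cls_mask = cohort.labels == cls
            sub_samples = [y[cls_mask & (g == d)] for d in dosages]
            sub_samples = [s for s in sub_samples if s.size >= 2]
            if len(sub_samples) >= 2:
                _, pc, _ = _rank_test(sub_samples)
                per_diag[cls] = pc
    return StratifiedTestResult(snp_id=snp_id, phenotype_id=phenotype_id,
                                groups=groups, statistic=stat, p_value=p,
                                test_name=name, alpha=alpha,
                                per_diagnosis_p=per_diag)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR), monotone and capped at 1.

    Off by default everywhere: single stratified tests report raw two-tailed
    p-values; apply this across a family of tests when screening many
    SNP-phenotype combinations.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise UsageError("p_values must be a non-empty 1-D array")
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    adjusted[order] = np.minimum.accumulate(
        (p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adjusted, 1.0)


# ---------------------------------------------------------------------------
# Importance ranking
# ---------------------------------------------------------------------------

def importance_ranking(attr: AttributionResult, top_k: int | None = None):
    """Features sorted by mean |Shapley value| descending; ties broken by
    feature name (ascending). top_k beyond the feature count returns all."""
    if attr.values.size == 0:
        raise DataError("empty attribution result")
    imp = attr.global_importance()
    names = np.array(attr.feature_names, dtype=object)
    order = np.lexsort((names, -imp))
    ranked = [(str(names[k]), float(imp[k])) for k in order]
    if top_k is not None:
        ranked = ranked[:max(0, int(top_k))]
    return ranked
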