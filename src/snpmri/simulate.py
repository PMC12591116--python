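"""Synthetic imaging-genetics cohort simulator with planted effects.

The generative model, per subject t:

* dosage g_tj ~ Binomial(2, maf_j)  (Hardy-Weinberg proportions p^2, 2pq, q^2);
* diagnosis: either drawn independently from the class prevalences, or — when
  liability SNPs are declared — assigned by thresholding a genetic liability
  l_t = sum_j gamma_j (g_tj - 2 maf_j) + eps_t, eps ~ N(0,1), with thresholds
  at the empirical liability quantiles matching the prevalences (so marginal
  class frequencies are preserved while dosages carry diagnostic signal);
* ROI value x_tr = baseline + sum over causal pairs beta (g) + class shift
  + optional genotype-by-diagnosis terms + N(0, noise_sd^2) noise.

Randomness is split into named substreams (genotypes / labels / noise), each
consumed column-by-column, so e.g. adding ROIs never perturbs genotype draws.
The returned manifest records every planted effect, which is what the
planted-effect recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CLASS_ORDER, CohortTable
from .errors import DataError

_SUBSTREAM = {"genotypes": 1, "labels": 2, "noise": 3}


@dataclass
class SyntheticSpec:
    """Ground-truth generative parameters for one synthetic cohort.

    causal_pairs: (snp_index, roi_index, beta) — additive ROI-units-per-alt-allele
    effects. class_shifts: diagnosis -> length-n_rois shift vector (e.g. negative
    values model atrophy in AD). liability_snps: (snp_index, gamma) weights of the
    genetic liability that drives diagnosis; empty -> labels independent of
    genotype. per_class_betas: (snp_index, roi_index, diagnosis, beta) genotype-by-
    diagnosis interaction effects.
    """

    n_subjects: int
    n_snps: int
    n_rois: int
    mafs: np.ndarray | float = 0.3
    causal_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    prevalences: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.48, "MCI": 0.24, "AD": 0.28})
    class_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    liability_snps: list[tuple[int, float]] = field(default_factory=list)
    per_class_betas: list[tuple[int, int, str, float]] = field(default_factory=list)
    noise_sd: np.ndarray | float = 1.0
    baseline: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1 or self.n_rois < 1:
            raise DataError("n_subjects, n_snps, n_rois must be positive")
        mafs = self.maf_array()
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise DataError("mafs must lie in (0, 0.5]")
        sd = self.noise_array()
        if np.any(sd <= 0):
            raise DataError("noise_sd must be positive")
        prev = self.prevalence_items()
        if any(p < 0 for _, p in prev):
            raise DataError("prevalences must be non-negative")
        if abs(sum(p for _, p in prev) - 1.0) > 1e-9:
            raise DataError("prevalences must sum to 1")
        for c, _ in prev:
            if c not in CLASS_ORDER:
                raise DataError(f"unknown diagnosis class {c!r}")
        for s, r, _ in self.causal_pairs:
            if not (0 <= s < self.n_snps and 0 <= r < self.n_rois):
                raise DataError(f"causal pair ({s},{r}) out of range")
        for s, _ in self.liability_snps:
            if not 0 <= s < self.n_snps:
                raise DataError(f"liability SNP index {s} out of range")
        for s, r, c, _ in self.per_class_betas:
            if not (0 <= s < self.n_snps and 0 <= r < self.n_rois):
                raise DataError(f"per-class beta ({s},{r}) out of range")
            if c not in CLASS_ORDER:
                raise DataError(f"per-class beta references unknown class {c!r}")
        for c, v in self.class_shifts.items():
            if c not in CLASS_ORDER:
                raise DataError(f"class shift for unknown class {c!r}")
            if np.asarray(v, dtype=float).shape != (self.n_rois,):
                raise DataError(f"class shift for {c!r} must have length n_rois")

    def maf_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mafs, dtype=float),
                               (self.n_snps,)).copy()

    def noise_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.noise_sd, dtype=float),
                               (self.n_rois,)).copy()

    def prevalence_items(self) -> list[tuple[str, float]]:
        """(class, prevalence) in canonical NC < MCI < AD order."""
        return [(c, float(self.prevalences[c])) for c in CLASS_ORDER
                if c in self.prevalences]


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), _SUBSTREAM[stream]]))


def _draw_labels(spec: SyntheticSpec, G: np.ndarray) -> np.ndarray:
    rng = _rng(spec, "labels")
    items = spec.prevalence_items()
    classes = [c for c, _ in items]
    prev = np.array([p for _, p in items])
    n = spec.n_subjects
    if not spec.liability_snps:
        return rng.choice(np.array(classes, dtype=object), size=n, p=prev)
    mafs = spec.maf_array()
    liab = rng.standard_normal(n)
    for s, gamma in spec.liability_snps:
        liab += gamma * (G[:, s] - 2.0 * mafs[s])
    # class boundaries at empirical liability quantiles matching prevalences;
    # severity increases with liability (NC lowest, AD highest)
    order = np.argsort(liab, kind="stable")
    bounds = np.floor(np.cumsum(prev) * n + 1e-9).astype(int)
    labels = np.empty(n, dtype=object)
    start = 0
    for cls, stop in zip(classes, bounds):
        labels[order[start:stop]] = cls
        start = stop
    labels[order[start:]] = classes[-1]
    return labels


def simulate_cohort(spec: SyntheticSpec):
    """Draw one cohort from `spec`. Returns (CohortTable, manifest DataFrame).

    Fully reproducible from spec.seed; the manifest lists every planted effect.
    """
    spec.validate()
    n, S, R = spec.n_subjects, spec.n_snps, spec.n_rois
    mafs = spec.maf_array()
    noise_sd = spec.noise_array()

    rng_g = _rng(spec, "genotypes")
    G = np.empty((n, S))
    for j in range(S):  # column-wise so extra SNPs never perturb earlier draws
        G[:, j] = rng_g.binomial(2, mafs[j], size=n)

    labels = _draw_labels(spec, G)

    rng_n = _rng(spec, "noise")
    X = np.empty((n, R))
    for r in range(R):
        X[:, r] = spec.baseline + noise_sd[r] * rng_n.standard_normal(n)
    for s, r, beta in spec.causal_pairs:
        X[:, r] += beta * G[:, s]
    for cls, shift in spec.class_shifts.items():
        X[labels == cls] += np.asarray(shift, dtype=float)
    for s, r, cls, beta in spec.per_class_betas:
        mask = labels == cls
        X[mask, r] += beta * G[mask, s]

    width = max(3, len(str(S)), len(str(R)))
    cohort = CohortTable(
        subject_ids=[f"sub{i:0{len(str(n))}d}" for i in range(n)],
        genotypes=G,
        snp_ids=[f"rs{j + 1:0{width}d}" for j in range(S)],
        imaging=X,
        roi_ids=[f"ROI{r + 1:0{width}d}" for r in range(R)],
        labels=labels,
    )

    rows = []
    for j in range(S):
        rows.append(("maf", cohort.snp_ids[j], "", "", mafs[j]))
    for r in range(R):
        rows.append(("noise_sd", "", cohort.roi_ids[r], "", noise_sd[r]))
    for cls, p in spec.prevalence_items():
        rows.append(("prevalence", "", "", cls, p))
    for s, r, beta in spec.causal_pairs:
        rows.append(("causal_pair", cohort.snp_ids[s], cohort.roi_ids[r], "", beta))
    for s, gamma in spec.liability_snps:
        rows.append(("liability", cohort.snp_ids[s], "", "", gamma))
    for cls, shift in spec.class_shifts.items():
        for r in np.flatnonzero(np.asarray(shift, dtype=float)):
            rows.append(("class_shift", "", cohort.roi_ids[r], cls, float(shift[r])))
    for s, r, cls, beta in spec.per_class_betas:
        rows.append(("per_class_beta", cohort.snp_ids[s], cohort.roi_ids[r], cls, beta))
    manifest = pd.DataFrame(
        rows, columns=["effect_type", "snp_id", "roi_id", "diagnosis", "value"])
    return cohort, manifest


def null_cohort(spec: SyntheticSpec) -> CohortTable:
    """Same sampling scheme with every planted effect zeroed: labels are
    independent of all features."""
    null_spec = replace(spec, causal_pairs=[], class_shifts={},
                        liability_snps=[], per_class_betas=[])
    cohort, _ = simulate_cohort(null_spec)
    return cohort


# ---------------------------------------------------------------------------
# Named study conditions used by the validation experiments
# ---------------------------------------------------------------------------

def strong_effect_spec(seed: int = 0, n_subjects: int = 600, n_snps: int = 50,
                       n_rois: int = 40, n_causal: int = 6) -> SyntheticSpec:
    """Strong-coupling cohort: `n_causal` SNP->ROI pairs with large additive
    effects (beta = 3 noise SDs per alt allele), the same SNPs driving a
    genetic liability for diagnosis, and progressive atrophy-like negative
    shifts on the causal ROIs (MCI half of AD). ADNI-like class mix."""
    shift_ad = np.zeros(n_rois)
    shift_mci = np.zeros(n_rois)
    shift_ad[:n_causal] = -2.0
    shift_mci[:n_causal] = -1.0
    return SyntheticSpec(
        n_subjects=n_subjects, n_snps=n_snps, n_rois=n_rois, mafs=0.3,
        causal_pairs=[(j, j, 3.0) for j in range(n_causal)],
        prevalences={"NC": 0.48, "MCI": 0.24, "AD": 0.28},
        class_shifts={"AD": shift_ad, "MCI": shift_mci},
        liability_snps=[(j, 1.0) for j in range(n_causal)],
        noise_sd=1.0, seed=seed,
    )


def recovery_spec(seed: int = 0, n_subjects: int = 500) -> SyntheticSpec:
    """Compact cohort for attribution studies: 20 SNPs x 15 ROIs with three
    diagnosis-causal SNPs (liability gamma = 2) and three diagnosis-causal
    ROIs (atrophy-like shifts, MCI half of AD), 6 causal features in total.

    No SNP->ROI pairs are planted here: Shapley values split credit between
    correlated features, so cross-modal redundancy would make planted-effect
    recovery ill-posed rather than merely harder. Each causal feature carries
    signal unique to itself."""
    n_rois = 15
    shift_ad = np.zeros(n_rois)
    shift_mci = np.zeros(n_rois)
    shift_ad[:3] = -2.0
    shift_mci[:3] = -1.0
    return SyntheticSpec(
        n_subjects=n_subjects, n_snps=20, n_rois=n_rois, mafs=0.3,
        causal_pairs=[],
        prevalences={"NC": 0.48, "MCI": 0.24, "AD": 0.28},
        class_shifts={"AD": shift_ad, "MCI": shift_mci},
        liability_snps=[(j, 2.0) for j in range(3)],
        noise_sd=1.0, seed=seed,
    )
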