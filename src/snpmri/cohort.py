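"""Cohort data model and I/O.

A cohort pairs three blocks over one ordered subject list: a genotype matrix
(additive alternate-allele dosages in {0,1,2}), an imaging-feature matrix
(real-valued regional measures such as volumes or surface areas), and a
diagnosis label per subject (NC / MCI / AD; binary cohorts use NC / AD).

Tables are UTF-8 delimited text with a `subject_id` first column; genotype
columns are rsIDs, imaging columns are ROI/IDP names. Genotypes can also be
extracted from a VCF (GT field, additive coding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

#: Canonical diagnosis order: cognitively normal, mild cognitive impairment,
#: Alzheimer's disease. Cohorts may use any subset of >= 2 classes.
CLASS_ORDER = ("NC", "MCI", "AD")

SPLIT_NAMES = ("train", "validation", "test")

MISSING_POLICIES = ("mode-impute", "drop-subject", "drop-snp")


def ordered_classes(labels) -> tuple[str, ...]:
    """Classes present in `labels`, in canonical NC < MCI < AD order."""
    present = set(str(x) for x in labels)
    unknown = present - set(CLASS_ORDER)
    if unknown:
        raise DataError(f"unknown diagnosis labels: {sorted(unknown)}")
    return tuple(c for c in CLASS_ORDER if c in present)


@dataclass
class CohortTable:
    """Aligned genotype / imaging / diagnosis blocks for one cohort.

    All three blocks share the row order given by `subject_ids`.
    """

    subject_ids: list[str]
    genotypes: np.ndarray          # (N, S) float, values in {0,1,2} (NaN only transiently)
    snp_ids: list[str]
    imaging: np.ndarray            # (N, R) float
    roi_ids: list[str]
    labels: np.ndarray             # (N,) str in CLASS_ORDER
    #: optional per-SNP allele metadata, rsID -> (ref, alt), used only for
    #: rendering genotype group names like GG/AG/AA
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise DataError("duplicate subject_ids in cohort")
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.imaging = np.asarray(self.imaging, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.genotypes.shape != (n, len(self.snp_ids)):
            raise DataError(
                f"genotype block {self.genotypes.shape} does not match "
                f"{n} subjects x {len(self.snp_ids)} SNPs"
            )
        if self.imaging.shape != (n, len(self.roi_ids)):
            raise DataError(
                f"imaging block {self.imaging.shape} does not match "
                f"{n} subjects x {len(self.roi_ids)} features"
            )
        if self.labels.shape != (n,):
            raise DataError("labels length does not match subject count")
        ordered_classes(self.labels)  # validates label values
        finite = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(~np.isnan(self.genotypes)
                              & ~np.isin(self.genotypes, (0.0, 1.0, 2.0)))
            i, j = bad[0]
            raise DataError(
                f"dosage {self.genotypes[i, j]!r} for subject "
                f"{self.subject_ids[i]!r}, SNP {self.snp_ids[j]!r} is not in {{0,1,2}}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def classes(self) -> tuple[str, ...]:
        return ordered_classes(self.labels)

    def subset(self, index) -> "CohortTable":
        """Row subset by integer or boolean index, preserving order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in idx],
            genotypes=self.genotypes[idx],
            imaging=self.imaging[idx],
            labels=self.labels[idx],
        )


@dataclass
class SplitIndex:
    """train / validation / test assignment, one tag per subject."""

    subject_ids: list[str]
    assignment: np.ndarray  # (N,) str in SPLIT_NAMES
    fractions: tuple[float, float, float]
    seed: int

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise UsageError(f"unknown split {split!r}; expected one of {SPLIT_NAMES}")
        return np.flatnonzero(self.assignment == split)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "split": self.assignment})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def _read_table(path, what: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype={0: str},
                         float_precision="round_trip")
    except FileNotFoundError:
        raise DataError(f"{what} file not found: {path}")
    if df.columns[0] != "subject_id":
        raise DataError(f"{what} file {path}: first column must be 'subject_id', "
                        f"got {df.columns[0]!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataError(f"{what} file {path}: duplicate subject_id {dup!r}")
    return df.set_index("subject_id")


def read_cohort(genotype_path, imaging_path, label_path,
                missing_policy: str = "mode-impute") -> CohortTable:
    """Read and align the three cohort tables.

    Subjects are restricted to those present in all three files, in
    lexicographically sorted order (deterministic regardless of file order).
    Missing dosages (empty cells or 'NA') are resolved per `missing_policy`:
    mode-impute (per-SNP modal dosage), drop-subject, or drop-snp.
    """
    if missing_policy not in MISSING_POLICIES:
        raise UsageError(f"missing_policy must be one of {MISSING_POLICIES}")
    geno = _read_table(genotype_path, "genotype")
    img = _read_table(imaging_path, "imaging")
    lab = _read_table(label_path, "label")
    if "diagnosis" not in lab.columns:
        raise DataError(f"label file {label_path} lacks a 'diagnosis' column")

    common = sorted(set(geno.index) & set(img.index) & set(lab.index))
    if not common:
        raise DataError("no subjects shared by the genotype, imaging, and label files")
    geno = geno.loc[common]
    img = img.loc[common]
    labels = lab.loc[common, "diagnosis"].astype(str).to_numpy(dtype=object)

    G = geno.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = geno.isna().to_numpy()
    bad = ~np.isnan(G) & ~np.isin(G, (0.0, 1.0, 2.0))
    non_numeric = np.isnan(G) & ~raw_na & geno.notna().to_numpy()
    if bad.any() or non_numeric.any():
        i, j = np.argwhere(bad | non_numeric)[0]
        raise DataError(
            f"invalid dosage {geno.iat[i, j]!r} at subject {common[i]!r}, "
            f"SNP {geno.columns[j]!r}: dosages must be 0, 1, or 2"
        )

    snp_ids = [str(c) for c in geno.columns]
    missing = np.isnan(G)
    if missing.any():
        if missing_policy == "drop-subject":
            keep = ~missing.any(axis=1)
            if not keep.any():
                raise DataError("drop-subject removed every subject")
            common = [s for s, k in zip(common, keep) if k]
            G, img, labels = G[keep], img.loc[keep], labels[keep]
        elif missing_policy == "drop-snp":
            keep = ~missing.any(axis=0)
            if not keep.any():
                raise DataError("drop-snp removed every SNP")
            snp_ids = [s for s, k in zip(snp_ids, keep) if k]
            G = G[:, keep]
        else:  # mode-impute
            for j in np.flatnonzero(missing.any(axis=0)):
                col = G[:, j]
                obs = col[~np.isnan(col)]
                if obs.size == 0:
                    raise DataError(f"SNP {snp_ids[j]!r} has no observed dosages")
                vals, counts = np.unique(obs, return_counts=True)
                col[np.isnan(col)] = vals[np.argmax(counts)]
        logger.info("resolved missing dosages with policy %s", missing_policy)

    X = img.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise DataError(f"non-numeric imaging value at subject {common[i]!r}, "
                        f"feature {img.columns[j]!r}")

    return CohortTable(
        subject_ids=list(common), genotypes=G, snp_ids=snp_ids,
        imaging=X, roi_ids=[str(c) for c in img.columns], labels=labels,
    )


def write_cohort(cohort: CohortTable, genotype_path, imaging_path, label_path) -> None:
    """Write the three cohort tables in the formats `read_cohort` accepts."""
    pd.DataFrame(cohort.genotypes.astype(int), index=cohort.subject_ids,
                 columns=cohort.snp_ids).rename_axis("subject_id") \
        .to_csv(genotype_path, sep="\t")
    pd.DataFrame(cohort.imaging, index=cohort.subject_ids,
                 columns=cohort.roi_ids).rename_axis("subject_id") \
        .to_csv(imaging_path, sep="\t", float_format="%.17g")
    pd.DataFrame({"diagnosis": cohort.labels}, index=cohort.subject_ids) \
        .rename_axis("subject_id").to_csv(label_path, sep="\t")


# ---------------------------------------------------------------------------
# VCF genotype extraction
# ---------------------------------------------------------------------------

def read_genotypes_vcf(vcf_path, snp_whitelist=None):
    """Extract an additive-dosage matrix from a VCF (GT field only).

    Dosage = count of alternate alleles in a diploid genotype: 0/0 -> 0,
    0/1 or 1/0 -> 1, 1/1 -> 2; ./., haploid calls, and alleles > 1 are
    flagged missing (NaN). Multiallelic records are skipped with a warning.

    Returns (matrix (N x S, NaN for missing), snp_ids, subject_ids).
    """
    from cyvcf2 import VCF

    whitelist = set(snp_whitelist) if snp_whitelist is not None else None
    vcf = VCF(str(vcf_path))
    subjects = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if whitelist is not None and rid not in whitelist:
            continue
        if len(rec.ALT) != 1:
            logger.warning("skipping multiallelic record %s (%d ALT alleles)",
                           rid, len(rec.ALT))
            continue
        col = np.full(len(subjects), np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                if len(alleles) != 2:
                    logger.warning("non-diploid GT for sample %s at %s; flagged missing",
                                   subjects[i], rid)
                continue
            if any(a > 1 for a in alleles):
                logger.warning("allele index > 1 for sample %s at %s; flagged missing",
                               subjects[i], rid)
                continue
            col[i] = float(sum(alleles))
        snp_ids.append(rid)
        cols.append(col)
    if not cols:
        raise DataError(f"no usable biallelic records in {vcf_path}")
    return np.column_stack(cols), snp_ids, subjects


# ---------------------------------------------------------------------------
# Cross-cohort harmonization and splitting
# ---------------------------------------------------------------------------

def harmonize_cohorts(a: CohortTable, b: CohortTable):
    """Restrict both cohorts to their shared rsIDs, in one common order.

    Matching is by rsID string only (no strand/allele harmonization).
    Imaging blocks and labels are untouched.
    """
    shared = sorted(set(a.snp_ids) & set(b.snp_ids))
    if not shared:
        raise DataError("the two cohorts share no SNP rsIDs")

    def restrict(c: CohortTable) -> CohortTable:
        pos = {s: i for i, s in enumerate(c.snp_ids)}
        cols = [pos[s] for s in shared]
        return replace(c, genotypes=c.genotypes[:, cols], snp_ids=list(shared))

    return restrict(a), restrict(b)


def _largest_remainder_counts(n: int, fractions) -> np.ndarray:
    """Integer split counts: floor quotas, leftovers by largest remainder
    (ties and exact-tie remainders resolved toward the earlier split, so
    residual subjects preferentially land in training)."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for _ in range(n - counts.sum()):
        k = int(np.argmax(rem))  # argmax takes the first maximum -> train wins ties
        counts[k] += 1
        rem[k] = -1.0
    return counts


def split_cohort(cohort: CohortTable, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                 stratify_by_label: bool = True) -> SplitIndex:
    """Randomly assign subjects to train/validation/test.

    Deterministic given `seed`. Counts follow the largest-remainder rule.
    With stratification, per-class proportions in each split match the
    cohort's within one subject per class.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise UsageError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise UsageError(f"fractions must sum to 1, got {sum(fractions)}")

    n = cohort.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B17]))
    assignment = np.empty(n, dtype=object)

    if stratify_by_label:
        # controlled rounding: global split totals follow the largest-remainder
        # rule exactly, while every class x split cell stays within one subject
        # of its proportional quota
        targets = _largest_remainder_counts(n, fractions)
        classes = cohort.classes
        class_idx = {c: np.flatnonzero(cohort.labels == c) for c in classes}
        counts = {c: np.floor(np.asarray(fractions) * class_idx[c].size)
                  .astype(int) for c in classes}
        split_deficit = targets - np.sum([counts[c] for c in classes], axis=0)
        class_deficit = {c: class_idx[c].size - counts[c].sum()
                         for c in classes}
        remainder = {(c, s): fractions[s] * class_idx[c].size - counts[c][s]
                     for c in classes for s in range(3)}
        # remainder-descending passes; split order breaks ties toward train
        cells = sorted(remainder, key=lambda cs: (-remainder[cs], cs[1]))
        for allow_any in (False, True):
            for c, s in cells:
                if class_deficit[c] > 0 and split_deficit[s] > 0 and \
                        (allow_any or remainder[(c, s)] > 0):
                    counts[c][s] += 1
                    class_deficit[c] -= 1
                    split_deficit[s] -= 1
        for c in classes:
            idx = class_idx[c].copy()
            rng.shuffle(idx)
            bounds = np.cumsum(counts[c])
            assignment[idx[:bounds[0]]] = "train"
            assignment[idx[bounds[0]:bounds[1]]] = "validation"
            assignment[idx[bounds[1]:]] = "test"
    else:
        idx = rng.permutation(n)
        counts = _largest_remainder_counts(n, fractions)
        bounds = np.cumsum(counts)
        assignment[idx[:bounds[0]]] = "train"
        assignment[idx[bounds[0]:bounds[1]]] = "validation"
        assignment[idx[bounds[1]:]] = "test"

    for frac, name in zip(fractions, SPLIT_NAMES):
        if frac > 0 and not (assignment == name).any():
            raise DataError(
                f"split {name!r} is empty although its fraction is {frac}; "
                f"cohort of {n} subjects is too small"
            )
    return SplitIndex(subject_ids=list(cohort.subject_ids),
                      assignment=assignment.astype(object),
                      fractions=fractions, seed=int(seed))


def read_split(path, cohort: CohortTable) -> SplitIndex:
    """Read a two-column subject_id / split table aligned to `cohort`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(zip(df["subject_id"], df["split"]))
    missing = [s for s in cohort.subject_ids if s not in mapping]
    if missing:
        raise DataError(f"split file lacks {len(missing)} cohort subjects "
                        f"(first: {missing[0]!r})")
    assignment = np.array([mapping[s] for s in cohort.subject_ids], dtype=object)
    bad = set(assignment) - set(SPLIT_NAMES)
    if bad:
        raise DataError(f"unknown split tags in file: {sorted(bad)}")
    return SplitIndex(list(cohort.subject_ids), assignment, (0.0, 0.0, 0.0), -1)
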