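"""Count-data model: tables, gene grouping, proportion conventions, n-score.

The unit of analysis is a two-condition count table whose rows are
sub-gene features (poly(A) isoforms, splicing exons, CRISPR sgRNAs) or
genes, and whose columns are replicate samples.  All downstream statistics
operate gene by gene on the sub-matrix of features belonging to that gene,
so the central plumbing here is the partition of a table into
:class:`GeneSubMatrix` objects and the three proportion conventions used to
turn counts into beta-distributed sequencing proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "GeneSubMatrix",
    "ProportionMatrix",
    "FEATURE_KINDS",
    "PROPORTION_CONVENTIONS",
    "group_by_gene",
    "proportions",
    "nscore",
]

FEATURE_KINDS = ("isoform", "exon", "sgrna", "gene")
PROPORTION_CONVENTIONS = (
    "per_gene_max_total",
    "per_gene_library",
    "gene_over_grand_total",
)


@dataclass
class CountTable:
    """A feature-by-sample count matrix with a two-condition design.

    Parameters
    ----------
    gene_ids, feature_ids
        Row identifiers; ``(gene_id, feature_id)`` pairs must be unique.
    counts
        Non-negative real matrix, shape ``(n_features, n_samples)``.
        Counts may be raw or RPKM/FPKM/TPM-normalized; no integer
        coercion is performed.
    samples
        Column names.
    sample_condition
        Mapping ``sample -> condition label``; exactly two distinct
        labels, each with at least two samples.  The first label in
        ``condition_names`` plays the role of condition A (differences
        are reported as A minus B).
    feature_kind
        One of ``{"isoform", "exon", "sgrna", "gene"}``.
    """

    gene_ids: np.ndarray
    feature_ids: np.ndarray
    counts: np.ndarray
    samples: list[str]
    sample_condition: dict[str, str]
    feature_kind: str = "isoform"
    condition_names: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        self.samples = list(self.samples)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} features x {len(self.samples)} samples"
            )
        if len(self.feature_ids) != len(self.gene_ids):
            raise ValueError("gene_ids and feature_ids differ in length")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        missing = [s for s in self.samples if s not in self.sample_condition]
        if missing:
            raise ValueError(f"design does not cover samples: {missing}")
        # preserve first-appearance order of condition labels: first = A
        seen: list[str] = []
        for s in self.samples:
            c = self.sample_condition[s]
            if c not in seen:
                seen.append(c)
        if len(seen) != 2:
            raise ValueError(f"exactly two conditions required, got {seen}")
        self.condition_names = (seen[0], seen[1])
        for c in seen:
            n = sum(self.sample_condition[s] == c for s in self.samples)
            if n < 2:
                raise ValueError(f"condition {c!r} has {n} replicate(s); need >= 2")
        pairs = list(zip(self.gene_ids, self.feature_ids))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(gene_id, feature_id) pairs must be unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array(
            [self.sample_condition[s] == condition for s in self.samples], dtype=bool
        )

    def condition_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean column masks ``(mask_A, mask_B)`` in design order."""
        a, b = self.condition_names
        return self.condition_mask(a), self.condition_mask(b)

    def nonzero_mask(self) -> np.ndarray:
        """Features with a non-zero count in at least one sample."""
        return self.counts.sum(axis=1) > 0

    def drop_all_zero(self) -> "CountTable":
        """Remove features that are zero in every sample.

        All-zero features are excluded before testing and before BH
        adjustment; only features with non-zero read counts across
        samples are carried into the multiple-testing correction.
        """
        keep = self.nonzero_mask()
        return CountTable(
            self.gene_ids[keep],
            self.feature_ids[keep],
            self.counts[keep],
            self.samples,
            self.sample_condition,
            self.feature_kind,
        )

    def sum_to_genes(self) -> "CountTable":
        """Collapse features to genes by summing counts within each gene."""
        subs = group_by_gene(self)
        gene_ids = [sub.gene_id for sub in subs]
        rows = [sub.counts.sum(axis=0) for sub in subs]
        return CountTable(
            np.array(gene_ids, dtype=object),
            np.array(gene_ids, dtype=object),
            np.vstack(rows),
            self.samples,
            self.sample_condition,
            "gene",
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "feature_id", self.feature_ids)
        df.insert(0, "gene_id", self.gene_ids)
        return df


@dataclass
class GeneSubMatrix:
    """Counts of one gene's features split by condition (A then B)."""

    gene_id: object
    counts_A: np.ndarray  # (n_g, m_A)
    counts_B: np.ndarray  # (n_g, m_B)
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts_A = np.atleast_2d(np.asarray(self.counts_A, dtype=float))
        self.counts_B = np.atleast_2d(np.asarray(self.counts_B, dtype=float))
        if self.counts_A.shape[0] != self.counts_B.shape[0]:
            raise ValueError("counts_A and counts_B must have equal row counts")
        if self.counts_A.shape[0] != len(self.feature_ids):
            raise ValueError("feature_ids length mismatch")

    @property
    def n_features(self) -> int:
        return self.counts_A.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """Features x (m_A + m_B) matrix, A columns first."""
        return np.hstack([self.counts_A, self.counts_B])


@dataclass
class ProportionMatrix:
    """Per-sample sequencing proportions under one of three conventions.

    ``flagged`` marks features whose divisor was zero in some column
    (proportions set to 0 there) or that are all-zero.
    """

    values: np.ndarray
    convention: str
    flagged: np.ndarray

    def __post_init__(self) -> None:
        if self.convention not in PROPORTION_CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")


def group_by_gene(table: CountTable) -> list[GeneSubMatrix]:
    """Partition a table into per-gene sub-matrices, in input gene order.

    Rows of a gene need not be contiguous; per-gene row order follows the
    input.  Concatenating the sub-matrices in order reproduces every input
    row exactly once.
    """
    mask_a, mask_b = table.condition_columns()
    order: list[object] = []
    rows: dict[object, list[int]] = {}
    for i, g in enumerate(table.gene_ids):
        if g not in rows:
            rows[g] = []
            order.append(g)
        rows[g].append(i)
    subs = []
    for g in order:
        idx = np.array(rows[g], dtype=int)
        subs.append(
            GeneSubMatrix(
                gene_id=g,
                counts_A=table.counts[np.ix_(idx, np.where(mask_a)[0])],
                counts_B=table.counts[np.ix_(idx, np.where(mask_b)[0])],
                feature_ids=table.feature_ids[idx],
            )
        )
    return subs


def _per_gene_library(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    col_tot = block.sum(axis=0)
    flagged_cols = col_tot == 0
    safe = np.where(flagged_cols, 1.0, col_tot)
    vals = block / safe
    vals[:, flagged_cols] = 0.0
    flagged = np.full(block.shape[0], bool(flagged_cols.any()))
    return vals, flagged


def proportions(sub: GeneSubMatrix, convention: str) -> ProportionMatrix:
    """Turn a gene's counts into sequencing proportions.

    ``per_gene_max_total`` (CRISPR sgRNA data): within each condition the
    divisor is the largest per-replicate gene total over that condition's
    replicates, shared by all columns of the condition — replicate-level
    total differences are treated as technical noise of a pre-designed
    sgRNA set.

    ``per_gene_library`` (isoform/exon data): each column is divided by
    its own gene total, removing library-size differences; proportions
    within a gene sum to 1 per column.

    ``gene_over_grand_total`` (gene-level test): applies to a table whose
    rows are already genes; each column is divided by its grand total.
    """
    if convention not in PROPORTION_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    A, B = sub.counts_A, sub.counts_B
    all_zero = (A.sum(axis=1) + B.sum(axis=1)) == 0

    if convention == "per_gene_library" or convention == "gene_over_grand_total":
        # gene_over_grand_total is the same column normalization applied to
        # a gene-level table (rows = genes, divisor = grand total per column)
        va, fa = _per_gene_library(A)
        vb, fb = _per_gene_library(B)
        vals = np.hstack([va, vb])
        flagged = fa | fb | all_zero
    else:  # per_gene_max_total
        div_a = A.sum(axis=0).max()
        div_b = B.sum(axis=0).max()
        va = A / div_a if div_a > 0 else np.zeros_like(A)
        vb = B / div_b if div_b > 0 else np.zeros_like(B)
        vals = np.hstack([va, vb])
        flagged = all_zero | np.full(A.shape[0], div_a == 0 or div_b == 0)
    return ProportionMatrix(values=vals, convention=convention, flagged=flagged)


def nscore(expression: np.ndarray, log2_input: bool = False) -> np.ndarray:
    """Heatmap normalization that equalizes row maxima.

    ``n_ij = y_ij * max(y) / max(y_i.)`` where ``max(y)`` is the global
    maximum and ``max(y_i.)`` the maximum of row *i*.  Unlike the z-score
    it never fabricates a signed contrast: every row's maximum is raised
    to the global maximum and within-row structure is preserved.  If
    ``log2_input``, values are first inverted via ``y = 2**x``.
    All-zero rows are left as zeros.
    """
    y = np.asarray(expression, dtype=float)
    if y.size == 0:
        raise ValueError("empty matrix")
    if log2_input:
        y = np.power(2.0, y)
    global_max = y.max()
    row_max = y.max(axis=1, keepdims=True)
    safe = np.where(row_max == 0, 1.0, row_max)
    out = y * global_max / safe
    out[np.broadcast_to(row_max == 0, out.shape)] = 0.0
    return out


def check_grand_totals(table: CountTable, rel_tol: float = 0.01) -> bool:
    """Warn when per-sample grand totals differ by more than ``rel_tol``.

    Normalized data are assumed to have equal totals across replicates;
    this is not enforced, only checked.
    """
    totals = table.counts.sum(axis=0)
    if totals.max() <= 0:
        return True
    spread = (totals.max() - totals.min()) / totals.max()
    if spread > rel_tol:
        warnings.warn(
            f"sample grand totals differ by {spread:.1%} (> {rel_tol:.0%}); "
            "counts may not be normalized",
            stacklevel=2,
        )
        return False
    return True
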