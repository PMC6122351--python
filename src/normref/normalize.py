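"""CPM normalization, low-count filtering, log transform and PCA-based QC.

CPM (counts per million) is defined on the full library: a gene's counts
divided by the sample's total counts, times 1e6.  Columns therefore sum to
1e6 before any gene subsetting; after subsetting, columns are deliberately
not renormalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import CountMatrix, ValidationError

__all__ = [
    "CpmMatrix",
    "FilterPolicy",
    "compute_cpm",
    "filter_low_counts",
    "log2_cpm",
    "qc_pca",
]


@dataclass(frozen=True)
class CpmMatrix:
    """Gene x sample matrix of counts-per-million values."""

    cpm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.cpm.to_numpy() < 0).any():
            raise ValidationError("CPM values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


@dataclass(frozen=True)
class FilterPolicy:
    """Keep a gene iff CPM > ``min_cpm`` in at least
    ``ceil(min_fraction_samples * n_samples)`` samples.

    The rule (CPM > 1 in >= 25% of samples by default) is a conventional
    low-count filter; both knobs are configurable.
    """

    min_cpm: float = 1.0
    min_fraction_samples: float = 0.25

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min_cpm) and self.min_cpm >= 0):
            raise ValidationError("min_cpm must be finite and >= 0")
        if not (0.0 <= self.min_fraction_samples <= 1.0):
            raise ValidationError("min_fraction_samples must be in [0, 1]")


def compute_cpm(counts: CountMatrix) -> CpmMatrix:
    """Counts-per-million normalization: cpm[g, s] = counts[g, s] / total_s * 1e6."""
    df = counts.counts
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total count")
    return CpmMatrix(df.div(totals, axis=1) * 1e6)


def filter_low_counts(cpm: CpmMatrix, policy: FilterPolicy = FilterPolicy()) -> set[str]:
    """Gene ids passing the low-count filter (a subset of ``cpm.gene_ids``)."""
    df = cpm.cpm
    needed = math.ceil(policy.min_fraction_samples * df.shape[1])
    n_above = (df.to_numpy() > policy.min_cpm).sum(axis=1)
    return set(df.index[n_above >= needed])


def log2_cpm(cpm: CpmMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Entrywise log2(CPM + pseudocount); pseudocount must be positive."""
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be > 0")
    df = cpm.cpm if isinstance(cpm, CpmMatrix) else cpm
    return np.log2(df + pseudocount)


def qc_pca(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component scores of samples for quality control.

    ``matrix`` is genes x samples (typically log2 CPM on the unfiltered gene
    universe).  Samples are mean-centered in gene space and projected onto the
    top principal axes.  Returns (scores, explained-variance fractions) where
    scores is samples x components.

    Degenerate case: if all samples coincide, scores and explained-variance
    fractions are all zero.
    """
    X = matrix.T.to_numpy(dtype=float)
    n_samples, n_genes = X.shape
    if n_components > min(n_samples, n_genes):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)="
            f"{min(n_samples, n_genes)}"
        )
    centered = X - X.mean(axis=0, keepdims=True)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    if np.allclose(centered, 0):
        scores = np.zeros((n_samples, n_components))
        evr = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), evr
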