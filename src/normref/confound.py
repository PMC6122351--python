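"""Confound analysis: asservation and adipocyte exclusion sets, overlap
statistics, and a lightweight group differential-expression stand-in.

The test engine here is a per-gene Welch two-sample t-test on log2 CPM with
Benjamini-Hochberg adjustment.  It is deliberately declared as such in the
output (``engine="welch_bh"``): it stands in for moderated count-model
frameworks (limma/voom, DESeq2) that the surrounding pipeline would use on
real data, and results are never labeled as coming from those.  Comparisons
between single samples (e.g. the two halves of one split specimen) admit no
replicate test and use the pure fold-change rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .normalize import CpmMatrix
from .utils import log2_ratio, round_half_up_percent
from .variability import ReferencePanel

__all__ = [
    "OverlapStats",
    "group_log2fc",
    "welch_bh_test",
    "asg_gene_set",
    "halved_sample_de",
    "overlap_stats",
    "geneset_enrichment",
]


def _frame(cpm: CpmMatrix | pd.DataFrame) -> pd.DataFrame:
    return cpm.cpm if isinstance(cpm, CpmMatrix) else cpm


def group_log2fc(
    cpm: CpmMatrix | pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2((mean CPM in A + eps) / (mean CPM in B + eps)).

    Antisymmetric by construction: swapping the groups negates the result.
    """
    df = _frame(cpm)
    if not samples_a or not samples_b:
        raise ValidationError("both groups must be nonempty")
    mean_a = df[list(samples_a)].mean(axis=1)
    mean_b = df[list(samples_b)].mean(axis=1)
    return pd.Series(
        log2_ratio(mean_a + pseudocount, mean_b + pseudocount), index=df.index
    )


def welch_bh_test(
    log2cpm: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    alpha: float = 0.05,
    log2fc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 CPM with Benjamini-Hochberg adjustment.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (difference
    of group means on the log2 scale), ``p_value``, ``q_value`` and
    ``called`` (q <= alpha and |log2fc| > log2fc_threshold).  Genes with
    zero variance in both groups and equal means get p = 1 by convention.
    The frame carries ``attrs["engine"] = "welch_bh"``.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("welch_bh_test requires >= 2 samples per group")
    a = log2cpm[list(samples_a)].to_numpy(dtype=float)
    b = log2cpm[list(samples_b)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    # zero variance in both groups: p is NaN; equal means -> no evidence
    p = np.where(np.isnan(p), np.where(log2fc == 0, 1.0, 0.0), p)
    q = multipletests(p, method="fdr_bh")[1]
    called = (q <= alpha) & (np.abs(log2fc) > log2fc_threshold)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": q, "called": called},
        index=log2cpm.index,
    )
    out.attrs["engine"] = "welch_bh"
    return out


def asg_gene_set(
    panel: ReferencePanel,
    fat_cpm: pd.DataFrame,
    log2fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    cv_threshold: float | None = None,
) -> set[str]:
    """Adipocyte-signature genes: breast-vs-fat confound exclusion set.

    Only genes that are stable in breast tissue (panel CV below the CV
    threshold) are eligible — a gene already too variable in breast carries
    no information about fat confounding and is pre-filtered.  Among the
    eligible genes, those whose |log2 fold change| between the panel's mean
    breast CPM and the mean fat CPM exceeds ``log2fc_threshold`` are
    returned.
    """
    threshold = panel.cv_threshold if cv_threshold is None else cv_threshold
    table = panel.table
    if set(table.index) != set(fat_cpm.index):
        raise ValidationError("panel and fat samples must share the gene universe")
    fat_mean = fat_cpm.mean(axis=1).reindex(table.index)
    fc = log2_ratio(table["mean_cpm"] + pseudocount, fat_mean + pseudocount)
    eligible = table["cv"].to_numpy() < threshold  # NaN -> False
    with np.errstate(invalid="ignore"):
        hit = np.abs(fc) > log2fc_threshold
    hit &= ~np.isnan(fc)
    return set(table.index[eligible & hit])


def halved_sample_de(
    half_a: pd.Series,
    half_b: pd.Series,
    high_cv_genes: Iterable[str],
    log2fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> set[str]:
    """Fold-change calls between the two halves of one split specimen.

    Genes in the previously identified high-CV set are filtered out first;
    of the rest, genes with |log2 fold change| above the threshold are
    returned.  Single samples admit no replicate test, so this is a pure
    fold-change rule.
    """
    if not half_a.index.equals(half_b.index):
        raise ValidationError("both halves must share the same gene universe")
    fc = log2_ratio(half_a + pseudocount, half_b + pseudocount)
    with np.errstate(invalid="ignore"):
        mask = np.abs(fc) > log2fc_threshold
    mask &= ~np.isnan(fc)
    return set(half_a.index[mask]) - set(high_cv_genes)


@dataclass(frozen=True)
class OverlapStats:
    """Venn-style overlap between two gene sets.

    ``percent_of_a`` is the intersection as an integer percentage of set A
    (half-up rounding of the exact rational), or None when A is empty.
    """

    n_a: int
    n_b: int
    n_intersection: int
    percent_of_a: int | None

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_a, self.n_b):
            raise ValidationError("intersection cannot exceed either set")


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    a, b = set(set_a), set(set_b)
    n_int = len(a & b)
    return OverlapStats(
        n_a=len(a),
        n_b=len(b),
        n_intersection=n_int,
        percent_of_a=round_half_up_percent(n_int, len(a)) if a else None,
    )


def geneset_enrichment(
    de_genes: Iterable[str], gene_set: Iterable[str], universe_size: int
) -> tuple[float, float]:
    """Enrichment of a gene set among called genes: odds ratio and
    one-sided hypergeometric tail p-value.

    The 2x2 table is (in set / not in set) x (called / not called) over a
    universe of ``universe_size`` genes.  Degenerate margins give p = 1.
    Returns ``(odds_ratio, p)``; the odds ratio is the sample odds ratio
    ad/bc, with inf when bc = 0 and ad > 0.
    """
    de = set(de_genes)
    members = set(gene_set)
    n, big_k, big_n = len(de), len(members), universe_size
    if n > big_n or big_k > big_n:
        raise ValidationError("sets cannot exceed the universe")
    k = len(de & members)
    a, b = k, n - k
    c, d = big_k - k, big_n - big_k - (n - k)
    if min(a + b, c + d, a + c, b + d) < 0:
        raise ValidationError("inconsistent 2x2 table")
    if n == 0 or big_k == 0 or n == big_n or big_k == big_n:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    if b * c == 0:
        odds = np.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return float(odds), p
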