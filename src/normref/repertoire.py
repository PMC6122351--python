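"""Immune-repertoire summaries: depth harmonization, per-chain aligned-read
fractions and clonotype counts, and between-group fold ratios.

The module consumes per-(sample, chain) alignment summaries in the shape an
immune-repertoire aligner exports (seven chains: TCR alpha/beta/gamma/delta
and immunoglobulin heavy/kappa/lambda).  Sequencing depth is harmonized to
the smallest library, mirroring read-level downsampling; here the
harmonization acts on count summaries, either by exact hypergeometric
subsampling (integer counts) or by expectation scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CHAINS, RepertoireRecord, ValidationError

__all__ = [
    "RepertoireSummary",
    "harmonize_depth",
    "subsample_counts",
    "chain_fractions",
    "group_mean_fractions",
    "group_fold_ratio",
]


def harmonize_depth(totals: Sequence[int]) -> int:
    """Common depth for a set of libraries: the smallest total read count."""
    if len(totals) == 0:
        raise ValidationError("harmonize_depth requires at least one library")
    if any(t <= 0 for t in totals):
        raise ValidationError("all totals must be positive")
    return int(min(totals))


def subsample_counts(
    counts: np.ndarray,
    depth: int,
    rng: np.random.Generator | None = None,
    mode: str = "hypergeometric",
) -> np.ndarray:
    """Rescale a vector of integer counts to a common depth.

    ``mode="hypergeometric"`` draws an exact without-replacement subsample
    (column sum equals ``depth`` exactly; requires an ``rng``);
    ``mode="scale"`` returns the expectation ``counts * depth / sum``.
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds library total {total}")
    if mode == "scale":
        return counts * (depth / total)
    if mode == "hypergeometric":
        if rng is None:
            raise ValidationError("hypergeometric subsampling requires an rng")
        return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)
    raise ValidationError(f"unknown subsampling mode {mode!r}")


@dataclass(frozen=True)
class RepertoireSummary:
    """Tidy per-(sample, chain) table with aligned-read fractions.

    Columns: sample_id, chain, aligned_reads, total_reads_downsampled,
    clonotype_count, fraction.
    """

    per_sample: pd.DataFrame

    def samples(self) -> list[str]:
        return sorted(self.per_sample["sample_id"].unique())


def chain_fractions(records: Sequence[RepertoireRecord]) -> RepertoireSummary:
    """Fraction of the harmonized library aligned to each chain, per sample.

    fraction = aligned_reads / total_reads_downsampled.  The result is
    invariant to record order (rows are sorted by sample then chain).
    """
    rows = [
        {
            "sample_id": r.sample_id,
            "chain": r.chain,
            "aligned_reads": r.aligned_reads,
            "total_reads_downsampled": r.total_reads_downsampled,
            "clonotype_count": r.clonotype_count,
            "fraction": r.fraction,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chain",
            "aligned_reads",
            "total_reads_downsampled",
            "clonotype_count",
            "fraction",
        ],
    )
    chain_order = {c: i for i, c in enumerate(CHAINS)}
    df = df.sort_values(
        ["sample_id", "chain"],
        key=lambda s: s.map(chain_order) if s.name == "chain" else s,
    ).reset_index(drop=True)
    return RepertoireSummary(per_sample=df)


def group_mean_fractions(
    summary: RepertoireSummary, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean aligned-read fraction per (group, chain).

    ``groups`` maps sample_id -> group label; samples without a label are
    dropped.  Returns a group x chain DataFrame.
    """
    df = summary.per_sample.copy()
    df["group"] = df["sample_id"].map(dict(groups))
    df = df.dropna(subset=["group"])
    pivot = df.pivot_table(index="group", columns="chain", values="fraction", aggfunc="mean")
    return pivot.reindex(columns=[c for c in CHAINS if c in pivot.columns])


def group_fold_ratio(
    summary: RepertoireSummary,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    chain: str,
) -> float:
    """Mean aligned-read fraction of a chain in group A divided by group B.

    Returns ``inf`` when the denominator group mean is zero (flagged
    infinite rather than raising, so tabulations can proceed).
    """
    if chain not in CHAINS:
        raise ValidationError(f"unknown chain {chain!r}")
    df = summary.per_sample
    sub = df[df["chain"] == chain].set_index("sample_id")["fraction"]
    mean_a = sub.reindex(list(samples_a)).mean()
    mean_b = sub.reindex(list(samples_b)).mean()
    if np.isnan(mean_a) or np.isnan(mean_b):
        raise ValidationError("every sample in both groups needs a record for the chain")
    if mean_b == 0:
        return math.inf
    return float(mean_a / mean_b)
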