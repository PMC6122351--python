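"""Low-variability reference panels for normal breast expression.

A reference panel summarizes one (asservation, kit) group of healthy normal
samples: per-gene mean CPM, coefficient of variation (CV = sd / mean of CPM
across samples), and two exclusion flags — TLV for genes exceeding the
pairwise log2 fold-change threshold in at least one patient-matched
left/right breast pair, and ASG for genes confounded by adipocyte content.
A gene is a trustworthy reference ("low variability") iff

    cv < cv_threshold  AND  NOT tlv  AND  NOT asg.

The default CV threshold of 0.30 is chosen so that, for normally
distributed expression, the central 95% interval of a gene's expression
spans at most a 4-fold range (log2 fold change of 2):
``cv_to_max_log2fc(0.30, 1.96) ~= 1.95 <= 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, SampleMeta, ValidationError, metadata_frame
from .normalize import CpmMatrix
from .utils import log2_ratio, round_half_up_percent

__all__ = [
    "VariabilityConfig",
    "ReferencePanel",
    "gene_cv",
    "cv_to_max_log2fc",
    "max_log2fc_to_cv",
    "matched_pair_log2fc",
    "tlv_gene_set",
    "build_reference_panel",
    "category_counts",
]


@dataclass(frozen=True)
class VariabilityConfig:
    """Thresholds governing the reference-panel construction.

    cv_threshold
        Genes with CV at or above this value are considered too variable to
        serve as a reference (default 0.30).
    z_95
        Normal quantile defining the confidence interval behind the
        CV <-> fold-change correspondence (default 1.96, i.e. 95%).
    pair_log2fc_threshold
        A gene whose |log2 fold change| between a patient's left and right
        breast exceeds this in at least one pair is flagged TLV (default 2).
    pair_pseudocount
        CPM offset used in pairwise ratios (default 0.5 CPM); 0 is allowed,
        in which case 0/0 genes get an undefined fold change and never
        enter the TLV set.
    """

    cv_threshold: float = 0.30
    z_95: float = 1.96
    pair_log2fc_threshold: float = 2.0
    pair_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (self.cv_threshold > 0 and self.z_95 > 0 and self.pair_log2fc_threshold > 0):
            raise ValidationError("thresholds must be positive")
        if not self.cv_threshold * self.z_95 < 1:
            raise ValidationError(
                "cv_threshold * z_95 must be < 1 (lower confidence bound must stay positive)"
            )
        if self.pair_pseudocount < 0:
            raise ValidationError("pair_pseudocount must be >= 0")


def gene_cv(cpm: pd.DataFrame) -> pd.Series:
    """Per-gene coefficient of variation of CPM across the group's samples.

    Uses the sample standard deviation (n - 1 denominator).  Genes with zero
    mean get CV = NaN (variability of an unexpressed gene is undefined).
    Requires at least two samples.
    """
    if cpm.shape[1] < 2:
        raise ValidationError("gene_cv requires at least 2 samples in the group")
    mean = cpm.mean(axis=1)
    sd = cpm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


def cv_to_max_log2fc(cv, z: float = 1.96):
    """Maximal log2 fold change across a group implied by a CV.

    For normally distributed expression with mean mu and sd = cv * mu, the
    central interval at normal quantile ``z`` is [mu(1 - z cv), mu(1 + z cv)];
    the log2 ratio of its upper to lower bound is

        log2((1 + z cv) / (1 - z cv)).

    Domain: 0 <= cv < 1/z (the lower bound must stay positive).
    """
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0) or np.any(cv >= 1.0 / z):
        raise ValidationError(f"cv must lie in [0, 1/z) = [0, {1.0 / z:.6g})")
    result = np.log2((1.0 + z * cv) / (1.0 - z * cv))
    return float(result) if result.ndim == 0 else result


def max_log2fc_to_cv(log2fc, z: float = 1.96):
    """Inverse of :func:`cv_to_max_log2fc`: the CV whose central interval
    spans exactly ``2**log2fc``-fold.

    Solving (1 + z c) = R (1 - z c) with R = 2**log2fc gives
    c = (R - 1) / (z (R + 1)).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    if np.any(log2fc < 0):
        raise ValidationError("log2fc must be >= 0")
    ratio = np.exp2(log2fc)
    result = (ratio - 1.0) / (z * (ratio + 1.0))
    return float(result) if result.ndim == 0 else result


def matched_pair_log2fc(
    cpm_left: pd.Series, cpm_right: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """Per-gene log2((CPM_left + eps) / (CPM_right + eps)) for one L/R pair.

    With eps = 0, genes unexpressed on both sides get NaN.
    """
    if not cpm_left.index.equals(cpm_right.index):
        raise ValidationError("left and right columns must share the same gene universe")
    return pd.Series(
        log2_ratio(cpm_left + pseudocount, cpm_right + pseudocount),
        index=cpm_left.index,
    )


def tlv_gene_set(
    pairs: Sequence[tuple[pd.Series, pd.Series]],
    config: VariabilityConfig = VariabilityConfig(),
) -> set[str]:
    """Genes exceeding the pairwise log2FC threshold in >= 1 left/right pair.

    The comparison is strict (|log2FC| must be *more than* the threshold);
    undefined fold changes (NaN) never qualify.
    """
    if not pairs:
        raise ValidationError("tlv_gene_set requires at least one pair")
    flagged: set[str] = set()
    for left, right in pairs:
        fc = matched_pair_log2fc(left, right, config.pair_pseudocount)
        mask = np.abs(fc.to_numpy()) > config.pair_log2fc_threshold
        mask &= ~np.isnan(fc.to_numpy())
        flagged.update(fc.index[mask])
    return flagged


@dataclass(frozen=True)
class ReferencePanel:
    """Per-gene reference statistics for one (asservation, kit) group.

    ``table`` is indexed by gene id with columns ``mean_cpm``, ``cv``
    (NaN when the gene is unexpressed in the group), ``tlv``, ``asg`` and
    ``low_variability``.
    """

    asservation: str
    kit: str
    table: pd.DataFrame
    n_samples: int
    cv_threshold: float = 0.30

    def __post_init__(self) -> None:
        required = {"mean_cpm", "cv", "tlv", "asg", "low_variability"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel table missing columns: {sorted(missing)}")
        cv = self.table["cv"].to_numpy()
        if np.nanmin(cv, initial=0.0) < 0:
            raise ValidationError("cv must be nonnegative where defined")

    @property
    def low_variability_genes(self) -> set[str]:
        return set(self.table.index[self.table["low_variability"]])


def build_reference_panel(
    cpm: CpmMatrix | pd.DataFrame,
    metadata: Sequence[SampleMeta] | pd.DataFrame,
    asservation: str,
    kit: str,
    tlv_set: Iterable[str] = (),
    asg_set: Iterable[str] = (),
    config: VariabilityConfig = VariabilityConfig(),
    tissue: str = "breast_normal",
) -> ReferencePanel:
    """Build the low-variability reference panel for one sample group.

    Selects samples with the given tissue, asservation and kit, computes
    per-gene mean CPM and CV, applies the TLV/ASG exclusion sets, and flags
    each gene ``low_variability`` iff cv < cv_threshold and the gene carries
    neither exclusion flag.  Genes with undefined CV are never low
    variability.
    """
    df = cpm.cpm if isinstance(cpm, CpmMatrix) else cpm
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    selector = (
        (meta["tissue"] == tissue)
        & (meta["asservation"] == asservation)
        & (meta["kit"] == kit)
    )
    samples = [s for s in meta.index[selector] if s in df.columns]
    if not samples:
        raise ValidationError(f"no samples in group ({tissue}, {asservation}, {kit})")
    if len(samples) < 2:
        raise ValidationError(
            f"group ({tissue}, {asservation}, {kit}) has {len(samples)} sample(s); need >= 2"
        )
    sub = df[samples]
    cv = gene_cv(sub)
    tlv = df.index.isin(set(tlv_set))
    asg = df.index.isin(set(asg_set))
    low = (cv.to_numpy() < config.cv_threshold) & ~tlv & ~asg  # NaN < thr is False
    table = pd.DataFrame(
        {
            "mean_cpm": sub.mean(axis=1),
            "cv": cv,
            "tlv": tlv,
            "asg": asg,
            "low_variability": low,
        },
        index=df.index,
    )
    return ReferencePanel(
        asservation=asservation,
        kit=kit,
        table=table,
        n_samples=len(samples),
        cv_threshold=config.cv_threshold,
    )


def category_counts(
    panel: ReferencePanel,
    annotations: Sequence[GeneAnnotation],
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Count low-variability genes overall and within each annotation.

    Returns a DataFrame indexed by category ("All genes" plus one row per
    annotation) with columns ``n_category`` (the percentage denominator:
    universe size for "All genes", annotation size otherwise), ``n_low``
    and ``percent`` (integer, half-up rounding; pd.NA when the denominator
    is zero).
    """
    low = panel.low_variability_genes
    universe = universe_size if universe_size is not None else len(panel.table)
    rows: list[tuple[str, int, int]] = [("All genes", universe, len(low))]
    for ann in annotations:
        rows.append((ann.name, len(ann.members), len(low & ann.members)))
    out = pd.DataFrame(rows, columns=["category", "n_category", "n_low"]).set_index("category")
    out["percent"] = pd.array(
        [round_half_up_percent(n_low, n_cat) for n_cat, n_low in zip(out["n_category"], out["n_low"])],
        dtype="Int64",
    )
    return out
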