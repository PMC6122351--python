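"""Tumor overexpression calls against a normal reference panel, reliability
annotation, and matching of overexpressed genes to inhibitors.

The drug matching consumes a *local* snapshot of a drug-gene interaction
database (a TSV in DGIdb-export shape); no live queries are made.  The
database's filter parameters become column filters: an allowed family of
"inhibitor-like" interaction types, the antineoplastic and clinically
actionable flags, and an expert-curated source trust level.

Each reported gene is annotated with its reliability as a biomarker:
``variability = high`` iff its CV in the normal panel exceeds the CV
threshold, or it carries the adipocyte-signature (ASG) or left/right
pair-variability (TLV) exclusion flag; otherwise ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .confound import group_log2fc, welch_bh_test
from .io import DrugInteraction, ValidationError
from .normalize import CpmMatrix, log2_cpm
from .utils import log2_ratio
from .variability import ReferencePanel

__all__ = [
    "DEFAULT_INHIBITOR_TYPES",
    "DrugSelectionConfig",
    "DrugReportRow",
    "single_sample_log2fc",
    "group_tumor_de",
    "variability_flag",
    "filter_interactions",
    "match_drugs",
    "report_frame",
]

#: Interaction-type tokens accepted as "inhibitor-like" by default.
DEFAULT_INHIBITOR_TYPES: frozenset[str] = frozenset(
    {
        "antagonist",
        "antibody",
        "blocker",
        "inhibitor",
        "suppressor",
        "allosteric modulator",
        "adduct",
        "binder",
        "immunotherapy",
        "inhibitory allosteric modulator",
        "inverse agonist",
        "vaccine",
    }
)


@dataclass(frozen=True)
class DrugSelectionConfig:
    """Parameters of the overexpression call and the interaction filter."""

    overexpression_log2fc_threshold: float = 1.5
    allowed_interaction_types: frozenset[str] = DEFAULT_INHIBITOR_TYPES
    require_antineoplastic: bool = True
    require_clinically_actionable: bool = True
    require_expert_curated: bool = True
    expert_trust_token: str = "expert curated"
    cv_threshold: float = 0.30
    pseudocount: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.overexpression_log2fc_threshold > 0:
            raise ValidationError("overexpression threshold must be > 0")
        if not self.allowed_interaction_types:
            raise ValidationError("allowed_interaction_types must be nonempty")


def single_sample_log2fc(
    tumor_cpm: pd.Series, panel: ReferencePanel, pseudocount: float = 0.5
) -> pd.Series:
    """Personalized fold change: one tumor column against the panel's mean
    normal CPM, per gene: log2((tumor + eps) / (panel mean + eps))."""
    mean_cpm = panel.table["mean_cpm"]
    if not tumor_cpm.index.equals(mean_cpm.index):
        tumor_cpm = tumor_cpm.reindex(mean_cpm.index)
        if tumor_cpm.isna().any():
            raise ValidationError("tumor sample and panel must share the gene universe")
    return pd.Series(
        log2_ratio(tumor_cpm + pseudocount, mean_cpm + pseudocount),
        index=mean_cpm.index,
    )


def group_tumor_de(
    tumor_cpm: CpmMatrix | pd.DataFrame,
    normal_cpm: CpmMatrix | pd.DataFrame,
    config: DrugSelectionConfig = DrugSelectionConfig(),
) -> pd.DataFrame:
    """Overexpression calls for a tumor group against a normal group.

    Welch/BH stand-in test on log2(CPM + 1) combined with the group fold
    change on CPM; a gene is called iff q <= alpha and its log2 fold change
    (tumor over normal) exceeds the overexpression threshold.  Only
    overexpression is called; underexpressed genes are reported with their
    negative log2fc but never called.
    """
    t_df = tumor_cpm.cpm if isinstance(tumor_cpm, CpmMatrix) else tumor_cpm
    n_df = normal_cpm.cpm if isinstance(normal_cpm, CpmMatrix) else normal_cpm
    if not t_df.index.equals(n_df.index):
        raise ValidationError("tumor and normal matrices must share the gene universe")
    joint = pd.concat([t_df, n_df], axis=1)
    log2 = log2_cpm(joint, 1.0)
    res = welch_bh_test(log2, list(t_df.columns), list(n_df.columns), alpha=config.alpha)
    fc = group_log2fc(joint, list(t_df.columns), list(n_df.columns), config.pseudocount)
    out = pd.DataFrame(
        {
            "log2fc": fc,
            "p_value": res["p_value"],
            "q_value": res["q_value"],
            "called": res["q_value"].to_numpy()
            <= config.alpha,
        },
        index=joint.index,
    )
    out["called"] &= out["log2fc"] > config.overexpression_log2fc_threshold
    out.attrs["engine"] = "welch_bh"
    return out


def variability_flag(
    cv: float, asg: bool, tlv: bool, cv_threshold: float = 0.30
) -> str:
    """Reliability label for a reported gene: ``"high"`` iff the gene's CV
    in normals exceeds the threshold, or it is ASG- or TLV-flagged;
    otherwise ``"low"``.  An undefined CV (NaN: gene unexpressed in the
    normals) is conservatively labeled high."""
    if asg or tlv:
        return "high"
    if np.isnan(cv):
        return "high"
    if cv < 0:
        raise ValidationError("cv must be nonnegative")
    return "high" if cv > cv_threshold else "low"


@dataclass(frozen=True)
class DrugReportRow:
    """One row of the overexpression/drug report (Gene, log2FC, CV, ASG,
    TLV, Variability, Inhibitors)."""

    gene: str
    log2fc: float
    cv: float
    asg: bool
    tlv: bool
    variability: str
    inhibitors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.inhibitors:
            raise ValidationError("a report row requires at least one inhibitor")
        if self.variability not in ("high", "low"):
            raise ValidationError("variability must be 'high' or 'low'")


def filter_interactions(
    interactions: Sequence[DrugInteraction], config: DrugSelectionConfig = DrugSelectionConfig()
) -> list[DrugInteraction]:
    """Interactions surviving the inhibitor filter, in input order:
    allowed interaction type, antineoplastic, clinically actionable and
    expert-curated source (each flag only when required by the config)."""
    kept = []
    for rec in interactions:
        if rec.interaction_type not in config.allowed_interaction_types:
            continue
        if config.require_antineoplastic and not rec.antineoplastic:
            continue
        if config.require_clinically_actionable and not rec.clinically_actionable:
            continue
        if config.require_expert_curated and rec.source_trust != config.expert_trust_token:
            continue
        kept.append(rec)
    return kept


def _qualifying_interactions(
    interactions: Sequence[DrugInteraction], config: DrugSelectionConfig
) -> dict[str, set[str]]:
    """gene -> set of drug names surviving the interaction filter."""
    by_gene: dict[str, set[str]] = {}
    for rec in filter_interactions(interactions, config):
        by_gene.setdefault(rec.gene, set()).add(rec.drug)
    return by_gene


def match_drugs(
    overexpressed: pd.Series | Mapping[str, float] | pd.DataFrame,
    panel: ReferencePanel,
    interactions: Sequence[DrugInteraction],
    config: DrugSelectionConfig = DrugSelectionConfig(),
) -> list[DrugReportRow]:
    """Match overexpressed genes to inhibitors and annotate reliability.

    ``overexpressed`` maps gene -> log2 fold change (a Series/dict, or a
    DE result frame with a ``log2fc`` column, restricted to its ``called``
    rows when present).  A row is emitted only for genes whose log2fc
    exceeds the overexpression threshold and for which at least one
    interaction survives the type/flag filters.  Inhibitor lists are
    deduplicated and alphabetically sorted; rows are ordered by descending
    log2fc, ties broken alphabetically by gene.
    """
    if isinstance(overexpressed, pd.DataFrame):
        df = overexpressed
        if "called" in df.columns:
            df = df[df["called"]]
        fc_map = dict(zip(df.index, df["log2fc"]))
    elif isinstance(overexpressed, pd.Series):
        fc_map = dict(overexpressed.items())
    else:
        fc_map = dict(overexpressed)

    drugs_by_gene = _qualifying_interactions(interactions, config)
    table = panel.table
    rows: list[DrugReportRow] = []
    for gene, fc in fc_map.items():
        if not fc > config.overexpression_log2fc_threshold:
            continue
        drugs = drugs_by_gene.get(gene)
        if not drugs:
            continue
        if gene in table.index:
            cv = float(table.at[gene, "cv"])
            asg = bool(table.at[gene, "asg"])
            tlv = bool(table.at[gene, "tlv"])
        else:
            cv, asg, tlv = float("nan"), False, False
        rows.append(
            DrugReportRow(
                gene=gene,
                log2fc=float(fc),
                cv=cv,
                asg=asg,
                tlv=tlv,
                variability=variability_flag(cv, asg, tlv, config.cv_threshold),
                inhibitors=tuple(sorted(drugs)),
            )
        )
    rows.sort(key=lambda r: (-r.log2fc, r.gene))
    return rows


def report_frame(rows: Sequence[DrugReportRow]) -> pd.DataFrame:
    """Report rows as a printable table with the conventional column layout
    (Gene, log2FC, CV, ASG, TLV, Variability, Inhibitor)."""
    return pd.DataFrame(
        {
            "Gene": [r.gene for r in rows],
            "log2FC": [r.log2fc for r in rows],
            "CV": [r.cv for r in rows],
            "ASG": ["Yes" if r.asg else "No" for r in rows],
            "TLV": ["Yes" if r.tlv else "No" for r in rows],
            "Variability": [r.variability for r in rows],
            "Inhibitor": ["; ".join(r.inhibitors) for r in rows],
        }
    )
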