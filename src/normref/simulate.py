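"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every stage — CPM normalization, CV-based reference panels, the
left/right pair filter, adipocyte-confound exclusion, tumor overexpression
calls and immune-repertoire contrasts — can be exercised against planted
truth, without any external download.

Count model
-----------
Counts are negative binomial via a gamma-Poisson mixture: each gene g has a
baseline relative expression (log2-normal across genes) and a biological
coefficient of variation cv_g drawn from a two-component mixture (stable
and variable genes).  For each sample, the expected relative profile is

    p = (1 - pi) * breast_profile + pi * fat_profile,

a convex mixture with adipocyte contamination fraction pi (nonzero for
fresh-frozen breast samples, emulating fat cells the surgeon could not
remove; formalin-fixed sections are fat-free).  Group effects are applied
multiplicatively before normalization: tumor spike genes, a fixation
(FFPE) gene-set effect, and a targeted-capture mask that zeroes untargeted
genes.  Per-gene gamma factors with variance cv_g^2 (shared between a
patient's left and right breast, plus a small per-sample residual) scale
the profile, which is renormalized and Poisson-sampled at the library size.
The marginal distribution of each count is then negative binomial with
dispersion cv_g^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CHAINS,
    CountMatrix,
    DrugInteraction,
    RepertoireRecord,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "RepertoireConfig",
    "InteractionTableConfig",
    "REFERENCE_INHIBITOR_PAIRS",
    "generate_cohort",
    "generate_repertoire",
    "generate_interaction_table",
]


def _default_groups() -> dict[tuple[str, str, str], int]:
    # mirrors the study design: 19 FFPE + 9 FF total-RNA normals, 11 FFPE
    # targeted normals, 10 FFPE total-RNA tumors, 6 FF targeted fat samples
    return {
        ("breast_normal", "FFPE", "total"): 19,
        ("breast_normal", "FF", "total"): 9,
        ("breast_normal", "FFPE", "targeted"): 11,
        ("breast_tumor", "FFPE", "total"): 10,
        ("fat", "FF", "targeted"): 6,
    }


def _default_pairs() -> dict[tuple[str, str], int]:
    # 7 left/right pairs among the FFPE total normals, 1 among the FF ones
    return {("FFPE", "total"): 7, ("FF", "total"): 1}


@dataclass(frozen=True)
class CohortConfig:
    """Design and noise parameters of a synthetic cohort.

    Defaults mirror the study design at desk scale: 2000 genes at 2-5M
    reads per library (per-gene depth comparable to 23686 genes at 20-80M
    reads), a two-component biological-CV mixture, adipocyte contamination
    pi ~ U(0.2, 0.6) in fresh-frozen breast samples, and planted
    fat-signature, left/right-discordant and tumor-spike gene sets.
    """

    seed: int
    n_genes: int = 2000
    groups: Mapping[tuple[str, str, str], int] = field(default_factory=_default_groups)
    n_pairs: Mapping[tuple[str, str], int] = field(default_factory=_default_pairs)
    library_size_range: tuple[int, int] = (2_000_000, 5_000_000)
    baseline_log2_cpm_mean: float = 6.0
    baseline_log2_cpm_sd: float = 2.0
    cv_high_fraction: float = 0.3
    cv_low_range: tuple[float, float] = (0.05, 0.20)
    cv_high_range: tuple[float, float] = (0.50, 1.00)
    residual_cv: float = 0.05
    fat_signature_size: int = 100
    fat_effect_range: tuple[float, float] = (3.0, 6.0)
    fat_up_fraction: float = 0.7
    contamination_range: tuple[float, float] = (0.2, 0.6)
    pair_discordant_size: int = 60
    pair_effect_range: tuple[float, float] = (2.5, 4.5)
    discordant_min_cpm: float = 20.0
    tumor_spike_size: int = 50
    tumor_spike_log2fc_range: tuple[float, float] = (2.0, 4.0)
    spike_min_cpm: float = 10.0
    targeted_mask_fraction: float = 0.2
    fixation_effect_size: int = 150
    fixation_effect_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for name in ("cv_high_fraction", "fat_up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        lo, hi = self.contamination_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("contamination_range must lie in [0, 1]")
        for name in (
            "fat_signature_size",
            "pair_discordant_size",
            "tumor_spike_size",
            "fixation_effect_size",
        ):
            if getattr(self, name) > self.n_genes:
                raise ValidationError(f"{name} cannot exceed n_genes")
        if not 0.0 <= self.targeted_mask_fraction < 1.0:
            raise ValidationError("targeted_mask_fraction must be in [0, 1)")
        if self.library_size_range[0] < 1 or self.library_size_range[0] > self.library_size_range[1]:
            raise ValidationError("invalid library_size_range")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    true_cv: pd.Series
    baseline_cpm: pd.Series
    fat_signature: dict[str, float]  # gene -> signed log2 effect (fat vs breast)
    pair_discordant: dict[str, tuple[str, str, float]]  # gene -> (pair_id, side, log2 effect)
    tumor_spikes: dict[str, float]  # gene -> log2 fold change in tumors
    fixation_effects: dict[str, float]  # gene -> signed log2 effect in FFPE
    masked_genes: frozenset[str]  # zeroed in targeted-kit libraries
    contamination: dict[str, float]  # sample_id -> pi


def _gamma_factors(rng: np.random.Generator, cv: np.ndarray) -> np.ndarray:
    """Mean-1 gamma factors with variance cv^2 (cv = 0 -> exactly 1)."""
    out = np.ones_like(cv)
    pos = cv > 0
    shape = 1.0 / cv[pos] ** 2
    out[pos] = rng.gamma(shape, cv[pos] ** 2)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, list[SampleMeta], SyntheticTruth]:
    """Generate a cohort (counts, metadata, truth), reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])

    base_log2 = rng.normal(config.baseline_log2_cpm_mean, config.baseline_log2_cpm_sd, n)
    w = np.exp2(base_log2)
    baseline_cpm = pd.Series(w / w.sum() * 1e6, index=genes)

    is_high = rng.random(n) < config.cv_high_fraction
    cv = np.where(
        is_high,
        rng.uniform(*config.cv_high_range, n),
        rng.uniform(*config.cv_low_range, n),
    )
    true_cv = pd.Series(cv, index=genes)

    # fat signature: planted on stable (low-CV) genes, mostly up in fat
    low_pool = genes[~is_high]
    if config.fat_signature_size > len(low_pool):
        raise ValidationError("fat_signature_size exceeds the low-CV gene pool")
    fat_genes = rng.choice(low_pool, config.fat_signature_size, replace=False)
    fat_mag = rng.uniform(*config.fat_effect_range, config.fat_signature_size)
    fat_sign = np.where(rng.random(config.fat_signature_size) < config.fat_up_fraction, 1.0, -1.0)
    fat_signature = dict(zip(fat_genes, fat_mag * fat_sign))

    fat_eff = np.zeros(n)
    fat_idx = pd.Index(genes).get_indexer(fat_genes)
    fat_eff[fat_idx] = fat_mag * fat_sign
    f = w * np.exp2(fat_eff)

    taken = set(fat_genes)

    # tumor spikes: planted on expressed genes, disjoint from the fat signature
    spike_pool = np.array(
        [g for g, c in zip(genes, baseline_cpm) if c >= config.spike_min_cpm and g not in taken]
    )
    if config.tumor_spike_size > len(spike_pool):
        raise ValidationError("tumor_spike_size exceeds the expressed gene pool")
    spike_genes = rng.choice(spike_pool, config.tumor_spike_size, replace=False)
    spike_fc = rng.uniform(*config.tumor_spike_log2fc_range, config.tumor_spike_size)
    tumor_spikes = dict(zip(spike_genes, spike_fc))
    taken |= set(spike_genes)

    # left/right discordant genes: each assigned to one side of one pair
    disc_pool = np.array(
        [
            g
            for g, c in zip(genes, baseline_cpm)
            if c >= config.discordant_min_cpm and g not in taken
        ]
    )
    if config.pair_discordant_size > len(disc_pool):
        raise ValidationError("pair_discordant_size exceeds the expressed gene pool")
    disc_genes = rng.choice(disc_pool, config.pair_discordant_size, replace=False)
    taken |= set(disc_genes)

    # fixation effect: multiplicative shift of a gene set in FFPE samples
    fix_pool = np.array([g for g in genes if g not in taken])
    fix_genes = rng.choice(
        fix_pool, min(config.fixation_effect_size, len(fix_pool)), replace=False
    )
    fix_mag = rng.uniform(*config.fixation_effect_range, len(fix_genes))
    fix_sign = np.where(rng.random(len(fix_genes)) < 0.5, 1.0, -1.0)
    fixation_effects = dict(zip(fix_genes, fix_mag * fix_sign))
    fix_eff = np.zeros(n)
    fix_eff[pd.Index(genes).get_indexer(fix_genes)] = fix_mag * fix_sign

    # targeted-capture mask: untargeted / non-coding genes absent from
    # exome-capture libraries
    n_masked = int(round(config.targeted_mask_fraction * n))
    masked = rng.choice(genes, n_masked, replace=False) if n_masked else np.array([], dtype=genes.dtype)
    masked_set = frozenset(masked)
    mask_idx = pd.Index(genes).get_indexer(masked) if n_masked else np.array([], dtype=int)

    # assemble samples group by group
    all_pairs: list[tuple[str, str, str]] = []  # (pair_id, left sample, right sample)
    metadata: list[SampleMeta] = []
    sample_plan: list[dict] = []
    patient_counter = 0
    prefix = {"breast_normal": "N", "breast_tumor": "T", "fat": "F"}
    kit_tag = {"total": "TOT", "targeted": "TGT"}

    for (tissue, ass, kit), size in config.groups.items():
        npairs = config.n_pairs.get((ass, kit), 0) if tissue == "breast_normal" else 0
        if 2 * npairs > size:
            raise ValidationError(f"group ({tissue}, {ass}, {kit}) too small for {npairs} pairs")
        tag = f"{prefix[tissue]}-{ass}-{kit_tag[kit]}"
        idx = 0
        for j in range(npairs):
            patient_counter += 1
            pid = f"P{patient_counter:03d}"
            pair_id = f"PAIR-{ass}-{kit_tag[kit]}-{j + 1}"
            members = []
            for side in ("L", "R"):
                idx += 1
                sid = f"{tag}-{idx:02d}"
                metadata.append(
                    SampleMeta(sid, tissue, ass, kit, pid, side=side, pair_id=pair_id)
                )
                sample_plan.append(
                    {"sid": sid, "tissue": tissue, "ass": ass, "kit": kit,
                     "patient": pid, "side": side, "pair_id": pair_id}
                )
                members.append(sid)
            all_pairs.append((pair_id, members[0], members[1]))
        for _ in range(size - 2 * npairs):
            patient_counter += 1
            pid = f"P{patient_counter:03d}"
            idx += 1
            sid = f"{tag}-{idx:02d}"
            metadata.append(SampleMeta(sid, tissue, ass, kit, pid))
            sample_plan.append(
                {"sid": sid, "tissue": tissue, "ass": ass, "kit": kit,
                 "patient": pid, "side": "NA", "pair_id": None}
            )

    # assign each discordant gene to one side of one pair
    pair_discordant: dict[str, tuple[str, str, float]] = {}
    if len(all_pairs) == 0 and config.pair_discordant_size > 0:
        disc_genes = np.array([], dtype=genes.dtype)
    for g in disc_genes:
        pair_id, left_sid, right_sid = all_pairs[rng.integers(len(all_pairs))]
        side = "L" if rng.random() < 0.5 else "R"
        mag = rng.uniform(*config.pair_effect_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pair_discordant[g] = (pair_id, side, mag * sign)

    # per-patient shared biological state (correlated left/right pairs)
    patient_factors: dict[str, np.ndarray] = {}

    spike_eff = np.zeros(n)
    spike_idx = pd.Index(genes).get_indexer(spike_genes)
    spike_eff[spike_idx] = spike_fc

    contamination: dict[str, float] = {}
    columns: dict[str, np.ndarray] = {}
    gene_index = pd.Index(genes)

    for plan in sample_plan:
        tissue, ass, kit, sid = plan["tissue"], plan["ass"], plan["kit"], plan["sid"]
        if tissue == "fat":
            base = f.copy()
        else:
            base = w.copy()
            if tissue == "breast_tumor":
                base *= np.exp2(spike_eff)
        if ass == "FFPE":
            base *= np.exp2(fix_eff)
        # planted left/right discordance
        if plan["pair_id"] is not None:
            for g, (pair_id, side, eff) in pair_discordant.items():
                if pair_id == plan["pair_id"] and side == plan["side"]:
                    base[gene_index.get_loc(g)] *= np.exp2(eff)
        fat_profile = f.copy()
        if ass == "FFPE":
            fat_profile *= np.exp2(fix_eff)
        if kit == "targeted":
            base[mask_idx] = 0.0
            fat_profile[mask_idx] = 0.0

        pi = 0.0
        if tissue == "breast_normal" and ass == "FF":
            pi = float(rng.uniform(*config.contamination_range))
        contamination[sid] = pi
        pb = base / base.sum()
        pfat = fat_profile / fat_profile.sum()
        p = (1.0 - pi) * pb + pi * pfat

        patient = plan["patient"]
        if patient not in patient_factors:
            patient_factors[patient] = _gamma_factors(rng, cv)
        bio = patient_factors[patient]
        residual = _gamma_factors(rng, np.full(n, config.residual_cv))
        noisy = p * bio * residual
        noisy /= noisy.sum()
        lib = int(rng.integers(config.library_size_range[0], config.library_size_range[1] + 1))
        columns[sid] = rng.poisson(noisy * lib)

    counts = pd.DataFrame(columns, index=genes)
    truth = SyntheticTruth(
        true_cv=true_cv,
        baseline_cpm=baseline_cpm,
        fat_signature=fat_signature,
        pair_discordant=pair_discordant,
        tumor_spikes=tumor_spikes,
        fixation_effects=fixation_effects,
        masked_genes=masked_set,
        contamination=contamination,
    )
    return CountMatrix(counts), metadata, truth


# ---------------------------------------------------------------------------
# immune repertoire
# ---------------------------------------------------------------------------

def _default_chain_fractions() -> dict[str, float]:
    # plausible bulk-tissue aligned-read fractions per chain
    return {
        "TRA": 4e-4,
        "TRB": 6e-4,
        "TRG": 5e-5,
        "TRD": 2e-5,
        "IGH": 1e-3,
        "IGK": 8e-4,
        "IGL": 6e-4,
    }


@dataclass(frozen=True)
class RepertoireConfig:
    """Parameters of the synthetic repertoire summary generator.

    Emulates the qualitative contrasts of interest: TCR-alpha depletion in
    exome-capture (targeted) libraries, globally scarce lymphocyte reads in
    pure fat tissue, and mild immunoglobulin depletion in fresh-frozen
    samples.
    """

    seed: int
    total_reads: int = 1_000_000
    baseline_fractions: Mapping[str, float] = field(default_factory=_default_chain_fractions)
    targeted_tra_factor: float = 0.1
    fat_factor: float = 0.03
    ff_ig_factor: float = 0.5
    noise_log2_sd: float = 0.4
    clonotype_rate: float = 0.05

    def __post_init__(self) -> None:
        missing = set(CHAINS) - set(self.baseline_fractions)
        if missing:
            raise ValidationError(f"baseline_fractions missing chains: {sorted(missing)}")


def generate_repertoire(
    metadata: Sequence[SampleMeta], config: RepertoireConfig
) -> list[RepertoireRecord]:
    """Per-(sample, chain) aligned-read counts at a common harmonized depth."""
    rng = np.random.default_rng(config.seed)
    records: list[RepertoireRecord] = []
    for meta in metadata:
        for chain in CHAINS:
            frac = config.baseline_fractions[chain]
            if meta.kit == "targeted" and chain == "TRA":
                frac *= config.targeted_tra_factor
            if meta.tissue == "fat":
                frac *= config.fat_factor
            if meta.asservation == "FF" and chain.startswith("IG"):
                frac *= config.ff_ig_factor
            frac *= float(np.exp2(rng.normal(0.0, config.noise_log2_sd)))
            aligned = int(rng.binomial(config.total_reads, min(frac, 1.0)))
            clonotypes = int(rng.binomial(aligned, config.clonotype_rate)) if aligned else 0
            records.append(
                RepertoireRecord(
                    sample_id=meta.sample_id,
                    chain=chain,
                    aligned_reads=aligned,
                    total_reads_downsampled=config.total_reads,
                    clonotype_count=clonotypes,
                )
            )
    return records


# ---------------------------------------------------------------------------
# drug-gene interaction fixture
# ---------------------------------------------------------------------------

#: Published gene-inhibitor associations used as the qualifying backbone of
#: the synthetic interaction snapshot.
REFERENCE_INHIBITOR_PAIRS: tuple[tuple[str, str], ...] = (
    ("TUBB3", "Ixabepilone"),
    ("TOP2A", "Doxorubicin"),
    ("RET", "Ponatinib"),
    ("ROS1", "Crizotinib"),
    ("RAD51", "Amuvatinib"),
    ("AURKB", "Danusertib"),
    ("AURKA", "Danusertib"),
    ("CHEK1", "AZD7762"),
    ("CHEK2", "AZD7762"),
    ("NOTCH1", "RO4929097"),
    ("PARP1", "Olaparib"),
    ("PIK3R2", "Apitolisib"),
    ("RRM1", "Gemcitabine"),
    ("SYK", "Fostamatinib"),
    ("CDK4", "Palbociclib"),
    ("AKT1", "AZD5363"),
    ("MAP2K1", "Cobimetinib"),
    ("ALK", "Crizotinib"),
    ("ERBB3", "Osimertinib"),
)

_DISQUALIFY_MODES = ("wrong_type", "not_antineoplastic", "not_actionable", "weak_source")


@dataclass(frozen=True)
class InteractionTableConfig:
    """Composition of the synthetic interaction snapshot."""

    seed: int
    include_reference_pairs: bool = True
    n_extra_qualifying: int = 0
    n_disqualified: int = 30

    def __post_init__(self) -> None:
        if self.n_disqualified < 0 or self.n_extra_qualifying < 0:
            raise ValidationError("record counts must be nonnegative")


def generate_interaction_table(
    config: InteractionTableConfig,
) -> tuple[list[DrugInteraction], list[DrugInteraction]]:
    """Interaction records mixing qualifying and planted disqualified rows.

    Returns ``(records, qualifying)`` where ``qualifying`` is exactly the
    subset that survives the default inhibitor filter (inhibitor-like type,
    antineoplastic, clinically actionable, expert curated).
    """
    rng = np.random.default_rng(config.seed)
    qualifying: list[DrugInteraction] = []
    if config.include_reference_pairs:
        for gene, drug in REFERENCE_INHIBITOR_PAIRS:
            qualifying.append(
                DrugInteraction(gene, drug, "inhibitor", True, True, "expert curated")
            )
    for i in range(config.n_extra_qualifying):
        qualifying.append(
            DrugInteraction(
                f"SYN{i:03d}", f"Synthodrug-{i:03d}", "inhibitor", True, True, "expert curated"
            )
        )
    disqualified: list[DrugInteraction] = []
    for i in range(config.n_disqualified):
        mode = _DISQUALIFY_MODES[i % len(_DISQUALIFY_MODES)]
        gene = (
            REFERENCE_INHIBITOR_PAIRS[int(rng.integers(len(REFERENCE_INHIBITOR_PAIRS)))][0]
            if rng.random() < 0.5
            else f"OFF{i:03d}"
        )
        drug = f"Nonqualib-{i:03d}"
        if mode == "wrong_type":
            rec = DrugInteraction(gene, drug, "agonist", True, True, "expert curated")
        elif mode == "not_antineoplastic":
            rec = DrugInteraction(gene, drug, "inhibitor", False, True, "expert curated")
        elif mode == "not_actionable":
            rec = DrugInteraction(gene, drug, "inhibitor", True, False, "expert curated")
        else:
            rec = DrugInteraction(gene, drug, "inhibitor", True, True, "curated")
        disqualified.append(rec)
    records = qualifying + disqualified
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, qualifying
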