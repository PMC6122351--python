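"""Plain-text tabular I/O for count matrices, sample metadata, gene lists,
drug-interaction tables and immune-repertoire summaries.

All formats are tab-separated UTF-8 with a header row (gene lists are one
identifier per line).  Gene identifiers are treated as opaque strings; no
identifier mapping is attempted.  Count matrices must be complete: missing
values are rejected, absent genes are absent rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SchemaError",
    "ParseError",
    "TISSUES",
    "ASSERVATIONS",
    "KITS",
    "SIDES",
    "CHAINS",
    "CountMatrix",
    "SampleMeta",
    "GeneAnnotation",
    "DrugInteraction",
    "RepertoireRecord",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "read_gene_list",
    "write_gene_list",
    "read_interactions",
    "write_interactions",
    "read_repertoire",
    "write_repertoire",
]


class ValidationError(ValueError):
    """A record or matrix violates a domain invariant."""


class SchemaError(ValueError):
    """A file is missing required columns."""


class ParseError(ValueError):
    """A cell could not be parsed as the required type."""


TISSUES = ("breast_normal", "breast_tumor", "fat")
ASSERVATIONS = ("FFPE", "FF")
KITS = ("total", "targeted")
SIDES = ("L", "R", "NA")
CHAINS = ("TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene ids and
    whose columns hold unique sample ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if df.isna().any().any():
            raise ValidationError("count matrix contains missing values")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            gi, si = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes-in-rows count matrix from TSV.

    The first column holds gene ids, the header row sample ids.  Malformed
    numbers raise :class:`ParseError` naming the offending cell; duplicate
    gene ids and negative counts raise :class:`ValidationError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    parsed = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].ne("")
        bad |= raw[col].eq("")
        if bad.any():
            gene = raw.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ParseError(f"malformed count at gene {gene!r}, sample {col!r}")
        parsed[col] = numeric
    df = pd.DataFrame(parsed, index=raw.index)
    return CountMatrix(df)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations: tissue, asservation method, kit, pairing."""

    sample_id: str
    tissue: str
    asservation: str
    kit: str
    patient_id: str
    side: str = "NA"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r} for {self.sample_id}")
        if self.asservation not in ASSERVATIONS:
            raise ValidationError(
                f"unknown asservation {self.asservation!r} for {self.sample_id}"
            )
        if self.kit not in KITS:
            raise ValidationError(f"unknown kit {self.kit!r} for {self.sample_id}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r} for {self.sample_id}")


_META_COLUMNS = ["sample_id", "tissue", "asservation", "kit", "patient_id", "side", "pair_id"]


def validate_pairing(records: Sequence[SampleMeta]) -> None:
    """Check the left/right pairing invariant over a metadata set.

    Paired samples share ``pair_id`` and ``patient_id`` and differ in side;
    every pair has exactly two members.
    """
    seen: dict[str, list[SampleMeta]] = {}
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    for rec in records:
        if rec.pair_id:
            seen.setdefault(rec.pair_id, []).append(rec)
    for pair_id, members in seen.items():
        if len(members) != 2:
            raise ValidationError(
                f"pair {pair_id!r} has {len(members)} samples, expected 2"
            )
        a, b = members
        if a.patient_id != b.patient_id:
            raise ValidationError(f"pair {pair_id!r} spans two patients")
        if {a.side, b.side} != {"L", "R"}:
            raise ValidationError(f"pair {pair_id!r} must have one L and one R sample")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata missing columns: {missing}")
    records = [
        SampleMeta(
            sample_id=row.sample_id,
            tissue=row.tissue,
            asservation=row.asservation,
            kit=row.kit,
            patient_id=row.patient_id,
            side=row.side or "NA",
            pair_id=row.pair_id or None,
        )
        for row in df.itertuples()
    ]
    validate_pairing(records)
    return records


def write_metadata(records: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {**dataclasses.asdict(r), "pair_id": r.pair_id or ""} for r in records
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[SampleMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (convenience view)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_META_COLUMNS)
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# gene annotation lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A named gene set, e.g. breast-cancer genes or cancer biomarkers."""

    name: str
    members: frozenset[str]

    def unmatched(self, universe: Iterable[str]) -> frozenset[str]:
        """Members absent from a declared gene universe."""
        return self.members - frozenset(universe)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneAnnotation:
    lines = Path(path).read_text().splitlines()
    members = frozenset(line.strip() for line in lines if line.strip())
    return GeneAnnotation(name=name or Path(path).stem, members=members)


def write_gene_list(annotation: GeneAnnotation | Iterable[str], path: str | Path) -> None:
    members = (
        annotation.members if isinstance(annotation, GeneAnnotation) else set(annotation)
    )
    Path(path).write_text("\n".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# drug-gene interactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugInteraction:
    """One row of a DGIdb-style local interaction snapshot."""

    gene: str
    drug: str
    interaction_type: str
    antineoplastic: bool
    clinically_actionable: bool
    source_trust: str

    def __post_init__(self) -> None:
        if not self.interaction_type or self.interaction_type != self.interaction_type.lower():
            raise ValidationError(
                f"interaction_type must be a non-empty lowercase token, "
                f"got {self.interaction_type!r}"
            )


_INTERACTION_COLUMNS = [
    "gene",
    "drug",
    "interaction_type",
    "antineoplastic",
    "clinically_actionable",
    "source_trust",
]

_BOOL_TOKENS = {"true": True, "false": False}


def _parse_bool(token: str, column: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(f"cannot parse {token!r} as boolean in column {column!r}") from None


def read_interactions(path: str | Path) -> list[DrugInteraction]:
    """Read a drug-gene interaction TSV, lowercasing interaction types.

    Record order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"interaction table missing columns: {missing}")
    return [
        DrugInteraction(
            gene=row.gene,
            drug=row.drug,
            interaction_type=row.interaction_type.strip().lower(),
            antineoplastic=_parse_bool(row.antineoplastic, "antineoplastic"),
            clinically_actionable=_parse_bool(row.clinically_actionable, "clinically_actionable"),
            source_trust=row.source_trust,
        )
        for row in df.itertuples()
    ]


def write_interactions(records: Sequence[DrugInteraction], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["antineoplastic"] = "true" if r.antineoplastic else "false"
        d["clinically_actionable"] = "true" if r.clinically_actionable else "false"
        rows.append(d)
    pd.DataFrame(rows, columns=_INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# immune repertoire summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepertoireRecord:
    """Aligned-read and clonotype summary for one (sample, chain).

    ``total_reads_downsampled`` is the common, depth-harmonized library size;
    invariants: aligned_reads <= total, clonotype_count <= aligned_reads.
    """

    sample_id: str
    chain: str
    aligned_reads: int
    total_reads_downsampled: int
    clonotype_count: int

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValidationError(f"unknown chain {self.chain!r}")
        if self.total_reads_downsampled <= 0:
            raise ValidationError("total_reads_downsampled must be positive")
        if not 0 <= self.aligned_reads <= self.total_reads_downsampled:
            raise ValidationError(
                f"aligned_reads out of range for {self.sample_id}/{self.chain}"
            )
        if not 0 <= self.clonotype_count <= self.aligned_reads:
            raise ValidationError(
                f"clonotype_count exceeds aligned_reads for {self.sample_id}/{self.chain}"
            )

    @property
    def fraction(self) -> float:
        return self.aligned_reads / self.total_reads_downsampled


_REPERTOIRE_COLUMNS = [
    "sample_id",
    "chain",
    "aligned_reads",
    "total_reads_downsampled",
    "clonotype_count",
]


def read_repertoire(path: str | Path) -> list[RepertoireRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REPERTOIRE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"repertoire table missing columns: {missing}")

    def _int(token: str, column: str) -> int:
        try:
            return int(token)
        except ValueError:
            raise ParseError(f"cannot parse {token!r} as integer in column {column!r}") from None

    return [
        RepertoireRecord(
            sample_id=row.sample_id,
            chain=row.chain,
            aligned_reads=_int(row.aligned_reads, "aligned_reads"),
            total_reads_downsampled=_int(row.total_reads_downsampled, "total_reads_downsampled"),
            clonotype_count=_int(row.clonotype_count, "clonotype_count"),
        )
        for row in df.itertuples()
    ]


def write_repertoire(records: Sequence[RepertoireRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=_REPERTOIRE_COLUMNS).to_csv(path, sep="\t", index=False)
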