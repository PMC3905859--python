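"""Sequences, gene catalogs, pathway annotations and pair classification.

The catalog model mirrors how pathway databases annotate genes: a gene owns
one or more polypeptides and one or more transcripts (isoforms), and pathway
memberships live on the gene; every protein-RNA pair drawn from the catalog
is *autogenous* (same gene), *intra-pathway* (different genes sharing at
least one pathway) or *inter-pathway* (annotated genes sharing none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
RNA_ALPHABET = frozenset("ACGUN")

#: inclusive length bounds applied before any prediction
DEFAULT_LENGTH_BOUNDS = {"protein": (50, 750), "transcript": (50, 1500)}


class Kind(str, Enum):
    PROTEIN = "protein"
    TRANSCRIPT = "transcript"


class PairClass(str, Enum):
    AUTOGENOUS = "autogenous"
    INTRA_PATHWAY = "intra_pathway"
    INTER_PATHWAY = "inter_pathway"


class FastaParseError(ValueError):
    pass


class UnclassifiablePairError(ValueError):
    """Raised when a heterologous pair has an unannotated gene on one side."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    gene_id: str
    kind: Kind
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == Kind.PROTEIN else RNA_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.kind.value} characters "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PathwayAnnotation:
    memberships: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, pws in self.memberships.items():
            if any(not p for p in pws):
                raise ValueError(f"gene {gene!r}: empty pathway_id")

    def pathways_of(self, gene_id: str) -> frozenset[str] | None:
        return self.memberships.get(gene_id)

    def pathway_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, pws in self.memberships.items():
            for p in pws:
                out.setdefault(p, set()).add(gene)
        return out

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PathwayAnnotation":
        memb: dict[str, set[str]] = {}
        for gene, pw in zip(df["gene_id"].astype(str), df["pathway_id"].astype(str)):
            memb.setdefault(gene, set()).add(pw)
        return cls({g: frozenset(p) for g, p in memb.items()})


@dataclass
class GeneCatalog:
    genes: set[str]
    proteins: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    annotation: PathwayAnnotation = field(
        default_factory=lambda: PathwayAnnotation({})
    )

    def __post_init__(self) -> None:
        for rec in (*self.proteins, *self.transcripts):
            if rec.gene_id not in self.genes:
                raise ValueError(
                    f"record {rec.id!r} references unknown gene {rec.gene_id!r}"
                )


def _normalize_sequence(seq: str, kind: Kind) -> str:
    seq = seq.upper()
    if kind == Kind.TRANSCRIPT:
        seq = seq.replace("T", "U")  # one alphabet internally
    return seq


def parse_header_id(header: str) -> str:
    """First whitespace-delimited token of a FASTA header (dialect-tolerant)."""
    return header.split()[0]


def _prescan_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header before sequence data"
                )
            return
    raise FastaParseError(f"{path}: empty file")


def load_fasta(
    path: str | Path,
    kind: Kind | str,
    gene_map: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read one :class:`SequenceRecord` per FASTA entry.

    Records whose id is missing from ``gene_map`` fall back to using their own
    id as ``gene_id`` (a warning is logged). Duplicate ids are an error.
    """
    kind = Kind(kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_fasta(path)
    gene_map = gene_map or {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_unmapped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        gene = gene_map.get(rid)
        if gene is None:
            gene = rid
            n_unmapped += 1
        records.append(
            SequenceRecord(
                id=rid,
                gene_id=gene,
                kind=kind,
                sequence=_normalize_sequence(str(entry.seq), kind),
            )
        )
    if n_unmapped:
        logger.warning(
            "%s: %d record(s) without gene_map entry; using record id as gene_id",
            path, n_unmapped,
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def load_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return dict(zip(df["record_id"], df["gene_id"]))


def load_annotation(path: str | Path) -> PathwayAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return PathwayAnnotation.from_table(df)


def write_annotation(annotation: PathwayAnnotation, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "pathway_id": p}
        for g, pws in sorted(annotation.memberships.items())
        for p in sorted(pws)
    ]
    pd.DataFrame(rows, columns=["gene_id", "pathway_id"]).to_csv(
        path, sep="\t", index=False
    )


def apply_length_filters(
    records: Iterable[SequenceRecord],
    bounds: Mapping[str, tuple[int, int]] | None = None,
) -> list[SequenceRecord]:
    """Keep records whose length lies within the inclusive bounds for their kind.

    Defaults: transcripts 50-1500 nt, proteins 50-750 aa (both ends included).
    """
    bounds = dict(DEFAULT_LENGTH_BOUNDS) | dict(bounds or {})
    kept: list[SequenceRecord] = []
    removed = 0
    for rec in records:
        lo, hi = bounds[rec.kind.value]
        if lo <= len(rec) <= hi:
            kept.append(rec)
        else:
            removed += 1
    if removed:
        logger.info("length filter removed %d record(s)", removed)
    return kept


def classify_pair(
    protein: SequenceRecord,
    rna: SequenceRecord,
    annotation: PathwayAnnotation,
) -> PairClass:
    """Classify a protein-RNA pair by its gene/pathway relationship."""
    if protein.gene_id == rna.gene_id:
        return PairClass.AUTOGENOUS
    pw_p = annotation.pathways_of(protein.gene_id)
    pw_r = annotation.pathways_of(rna.gene_id)
    if pw_p is None or pw_r is None:
        raise UnclassifiablePairError(
            f"pair ({protein.id}, {rna.id}): gene without pathway annotation"
        )
    if pw_p & pw_r:
        return PairClass.INTRA_PATHWAY
    return PairClass.INTER_PATHWAY


def enumerate_pairs(
    catalog: GeneCatalog,
    mode: str = "all",
) -> Iterator[tuple[SequenceRecord, SequenceRecord, PairClass]]:
    """Stream every retained protein x transcript combination, classified.

    Deterministic order (protein id, then rna id). Heterologous pairs in
    which either gene lacks annotation are skipped; the skipped count is
    logged after exhaustion.
    """
    if mode not in ("all", "autogenous_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if not catalog.proteins or not catalog.transcripts:
        return
    skipped = 0
    for prot in sorted(catalog.proteins, key=lambda r: r.id):
        for rna in sorted(catalog.transcripts, key=lambda r: r.id):
            if mode == "autogenous_only" and prot.gene_id != rna.gene_id:
                continue
            try:
                cls = classify_pair(prot, rna, catalog.annotation)
            except UnclassifiablePairError:
                skipped += 1
                continue
            yield prot, rna, cls
    if skipped:
        logger.info("enumerate_pairs skipped %d unclassifiable pair(s)", skipped)
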