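"""The gene partition: which relationship class dominates each gene's
high-propensity interactions, as a function of the propensity threshold.

For a threshold pi, only pairs with propensity strictly greater than pi are
counted.  Each gene with at least one surviving pair is assigned to the
class (autogenous / intra-pathway / inter-pathway) in which it is most
enriched.  Enrichment is class-normalized by default: the gene's share of
all surviving pairs of that class, so that globally abundant classes do not
swamp rare ones.  A raw-count mode is also available.  Ties go to the fixed
priority autogenous > intra > inter and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import PairClass

logger = logging.getLogger(__name__)

#: fixed class order used everywhere (also the tie-break priority)
CLASS_ORDER: tuple[PairClass, ...] = (
    PairClass.AUTOGENOUS,
    PairClass.INTRA_PATHWAY,
    PairClass.INTER_PATHWAY,
)


@dataclass(frozen=True)
class ScoredPair:
    protein_id: str
    rna_id: str
    protein_gene: str
    rna_gene: str
    pair_class: PairClass
    pi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pi):
            raise ValueError("propensity must be finite")
        if (self.pair_class == PairClass.AUTOGENOUS) != (
            self.protein_gene == self.rna_gene
        ):
            raise ValueError("pair_class inconsistent with gene ids")

    @property
    def gene_ids(self) -> tuple[str, str]:
        return (self.protein_gene, self.rna_gene)


@dataclass(frozen=True)
class PartitionCurve:
    thresholds: np.ndarray  # increasing
    fractions: np.ndarray  # (n thresholds, 3) gene fractions, CLASS_ORDER
    n_genes: np.ndarray  # assignable genes per threshold
    tail_counts: np.ndarray  # (n thresholds, 3) raw pair counts above threshold
    mode: str = "class_normalized"

    def __post_init__(self) -> None:
        ok = self.n_genes > 0
        sums = self.fractions[ok].sum(axis=1)
        if ok.any() and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 where genes are assignable")


def count_above(
    pairs: Sequence[ScoredPair], pi: float, cls: PairClass
) -> tuple[int, float]:
    """Pairs of class ``cls`` with propensity strictly above ``pi``.

    The fraction is relative to all pairs of that class; it is NaN (flagged)
    when the class is empty.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    total = sum(1 for p in pairs if p.pair_class == cls)
    count = sum(1 for p in pairs if p.pair_class == cls and p.pi > pi)
    if total == 0:
        logger.warning("no pairs of class %s: fraction undefined", cls.value)
        return count, float("nan")
    return count, count / total


def gene_partition(
    pairs: Sequence[ScoredPair],
    thresholds: Iterable[float],
    mode: str = "class_normalized",
) -> PartitionCurve:
    """Per-threshold gene fractions assigned to each relationship class."""
    if mode not in ("class_normalized", "raw_counts"):
        raise ValueError(f"unknown mode {mode!r}")
    thresholds = np.asarray(list(thresholds), dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted increasing")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pairs must be non-empty")

    genes = sorted(
        {p.protein_gene for p in pairs} | {p.rna_gene for p in pairs}
    )
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes_total = len(genes)
    pi = np.array([p.pi for p in pairs])
    cls = np.array([CLASS_ORDER.index(p.pair_class) for p in pairs])
    gp = np.array([gidx[p.protein_gene] for p in pairs])
    gr = np.array([gidx[p.rna_gene] for p in pairs])

    n_thr = len(thresholds)
    fractions = np.full((n_thr, 3), np.nan)
    n_genes = np.zeros(n_thr, dtype=int)
    tail_counts = np.zeros((n_thr, 3), dtype=int)
    n_ties = 0

    for t, thr in enumerate(thresholds):
        above = pi > thr  # strict, "higher than"
        per_gene = np.zeros((n_genes_total, 3))
        for c in range(3):
            sel = above & (cls == c)
            tail_counts[t, c] = int(sel.sum())
            np.add.at(per_gene[:, c], gp[sel], 1.0)
            hetero = sel & (gp != gr)
            np.add.at(per_gene[:, c], gr[hetero], 1.0)
        assignable = per_gene.sum(axis=1) > 0
        n_genes[t] = int(assignable.sum())
        if n_genes[t] == 0:
            continue
        score = per_gene.copy()
        if mode == "class_normalized":
            # normalize by surviving PAIR counts per class, so a gene's share
            # is its fraction of all above-threshold pairs of that class
            totals = tail_counts[t].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(totals > 0, per_gene / totals, 0.0)
        sub = score[assignable]
        best = sub.max(axis=1, keepdims=True)
        n_ties += int(((sub == best).sum(axis=1) > 1).sum())
        assigned = sub.argmax(axis=1)  # first max wins: priority order
        counts = np.bincount(assigned, minlength=3)
        fractions[t] = counts / n_genes[t]

    if n_ties:
        logger.info(
            "gene_partition: %d gene-threshold tie(s) resolved by class priority",
            n_ties,
        )
    return PartitionCurve(
        thresholds=thresholds,
        fractions=fractions,
        n_genes=n_genes,
        tail_counts=tail_counts,
        mode=mode,
    )


_REPORT_COLUMNS = [
    "threshold",
    "n_genes",
    "frac_autogenous",
    "frac_intra_pathway",
    "frac_inter_pathway",
    "count_autogenous",
    "count_intra_pathway",
    "count_inter_pathway",
]


def partition_report(curve: PartitionCurve) -> pd.DataFrame:
    """One row per threshold; undefined fractions are NaN (written as 'NA')."""
    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "n_genes": curve.n_genes,
            "frac_autogenous": curve.fractions[:, 0],
            "frac_intra_pathway": curve.fractions[:, 1],
            "frac_inter_pathway": curve.fractions[:, 2],
            "count_autogenous": curve.tail_counts[:, 0],
            "count_intra_pathway": curve.tail_counts[:, 1],
            "count_inter_pathway": curve.tail_counts[:, 2],
        },
        columns=_REPORT_COLUMNS,
    )


def write_partition_report(
    curve: PartitionCurve, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# mode: {curve.mode}\n")
        partition_report(curve).to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_partition_report(path: str | Path) -> PartitionCurve:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    mode = "class_normalized"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# mode:"):
                mode = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    return PartitionCurve(
        thresholds=df["threshold"].to_numpy(dtype=float),
        fractions=df[
            ["frac_autogenous", "frac_intra_pathway", "frac_inter_pathway"]
        ].to_numpy(dtype=float),
        n_genes=df["n_genes"].to_numpy(dtype=int),
        tail_counts=df[
            ["count_autogenous", "count_intra_pathway", "count_inter_pathway"]
        ].to_numpy(dtype=int),
        mode=mode,
    )


def write_scored_pairs(
    pairs: Sequence[ScoredPair], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in pairs],
            "rna_id": [p.rna_id for p in pairs],
            "protein_gene": [p.protein_gene for p in pairs],
            "rna_gene": [p.rna_gene for p in pairs],
            "class": [p.pair_class.value for p in pairs],
            "propensity": [p.pi for p in pairs],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_scored_pairs(path: str | Path) -> list[ScoredPair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ScoredPair(
            protein_id=str(r.protein_id),
            rna_id=str(r.rna_id),
            protein_gene=str(r.protein_gene),
            rna_gene=str(r.rna_gene),
            pair_class=PairClass(rcls),
            pi=float(r.propensity),
        )
        for r, rcls in zip(df.itertuples(), df["class"])
    ]
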