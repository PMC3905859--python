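"""Translation-efficiency feedback analysis.

Translation efficiency is the ratio of protein abundance to RNA abundance,
both in parts per million; a ratio below 1 reads as reduced efficiency, the
signature of an active negative feedback loop.  Genes are binned by RNA
abundance (log-spaced quartiles by default), split at ratio = 1, and the
mean +/- sd gene-level autogenous interaction propensity is reported per
bin and group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import build_ranking
from .partition import ScoredPair

logger = logging.getLogger(__name__)

GROUP_LOW = "ratio<1"
GROUP_HIGH = "ratio>=1"


@dataclass(frozen=True)
class AbundanceRecord:
    gene_id: str
    protein_ppm: float
    rna_ppm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.protein_ppm) and np.isfinite(self.rna_ppm)):
            raise ValueError("abundances must be finite")
        if self.protein_ppm < 0 or self.rna_ppm < 0:
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class FeedbackTable:
    bin_edges: np.ndarray
    rows: pd.DataFrame  # bin, bin_lo, bin_hi, group, n, mean_pi, sd_pi

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def _nonzero_mean(values: np.ndarray) -> float:
    positive = values[values > 0]
    return float(positive.mean()) if positive.size else 0.0


def load_abundances(
    protein_path: str | Path, rna_path: str | Path
) -> list[AbundanceRecord]:
    """Join protein and RNA abundance tables on gene_id.

    Each table has a ``gene_id`` column plus one or more numeric per-sample
    (tissue) columns.  The per-gene abundance is the mean of the strictly
    positive values; genes whose RNA columns are all zero are excluded
    (logged), since a ratio cannot be formed for them.
    """
    out: list[AbundanceRecord] = []
    tables = {}
    for key, path in (("protein", protein_path), ("rna", rna_path)):
        df = pd.read_csv(path, sep="\t", comment="#")
        numeric = df.drop(columns=["gene_id"]).to_numpy(dtype=float)
        if np.any(numeric < 0):
            raise ValueError(f"{path}: negative abundance")
        tables[key] = {
            str(g): _nonzero_mean(row)
            for g, row in zip(df["gene_id"], numeric)
        }
    n_zero_rna = 0
    for gene, protein_ppm in tables["protein"].items():
        rna_ppm = tables["rna"].get(gene)
        if rna_ppm is None:
            continue
        if rna_ppm == 0.0:
            n_zero_rna += 1
            continue
        out.append(AbundanceRecord(gene, protein_ppm, rna_ppm))
    if n_zero_rna:
        logger.info("excluded %d gene(s) with all-zero RNA abundance", n_zero_rna)
    return out


def translation_efficiency(rec: AbundanceRecord) -> float:
    """protein_ppm / rna_ppm; zero protein (undetected) yields ratio 0."""
    if rec.rna_ppm <= 0:
        raise ValueError(f"{rec.gene_id}: rna_ppm must be > 0")
    return rec.protein_ppm / rec.rna_ppm


def default_bin_edges(rna_ppm: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Log-spaced quantile edges of the RNA abundance distribution."""
    logs = np.log10(rna_ppm)
    edges = np.unique(np.quantile(logs, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([logs.min() - 0.5, logs.max() + 0.5])
    return 10.0 ** edges


def feedback_analysis(
    records: Sequence[AbundanceRecord],
    pairs: Sequence[ScoredPair],
    bin_edges: Sequence[float] | None = None,
    agg: str = "max",
) -> FeedbackTable:
    """Mean autogenous propensity per RNA-abundance bin and efficiency group.

    Genes must join across the abundance records and the autogenous pairs;
    within each RNA-abundance bin they split at translation-efficiency
    ratio 1 (a ratio of exactly 1 goes to the high-efficiency group).
    Empty cells are kept and flagged with n = 0.
    """
    ranking = build_ranking(pairs, agg=agg)
    propensity = dict(zip(ranking.genes, ranking.metric))
    joined = [r for r in records if r.gene_id in propensity]
    if not joined:
        raise ValueError("no gene joins abundance records with scored pairs")
    rna = np.array([r.rna_ppm for r in joined])
    ratio = np.array([translation_efficiency(r) for r in joined])
    pi = np.array([propensity[r.gene_id] for r in joined])
    edges = (
        np.asarray(list(bin_edges), dtype=float)
        if bin_edges is not None
        else default_bin_edges(rna)
    )
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    # right-open bins, last bin closed on the right
    bin_idx = np.clip(np.digitize(rna, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        for group, mask_group in (
            (GROUP_LOW, ratio < 1.0),
            (GROUP_HIGH, ratio >= 1.0),
        ):
            sel = (bin_idx == b) & mask_group
            n = int(sel.sum())
            rows.append(
                {
                    "bin": b,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "group": group,
                    "n": n,
                    "mean_pi": float(pi[sel].mean()) if n else np.nan,
                    "sd_pi": float(pi[sel].std(ddof=0)) if n else np.nan,
                }
            )
    return FeedbackTable(bin_edges=edges, rows=pd.DataFrame(rows))


def write_feedback_table(
    table: FeedbackTable, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.rows.to_csv(fh, sep="\t", index=False, na_rep="NA")
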