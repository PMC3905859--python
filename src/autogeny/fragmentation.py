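"""Fragment-level interaction maps localizing binding regions.

Overlapping windows of the protein and the transcript are scored against
each other; a per-position profile then assigns every residue/nucleotide the
best score among the windows covering it (max, not mean, so sharp binding
regions are not diluted), and binding regions are called as maximal runs of
positions at or above a quantile of that profile.

Coordinates are 0-based half-open internally; report writers emit 1-based
inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_PROTEIN_WINDOW = 50
DEFAULT_PROTEIN_STEP = 25
DEFAULT_RNA_WINDOW = 100
DEFAULT_RNA_STEP = 50


def _windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        logger.warning("step %d > window %d: coverage gaps", step, window)
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    out = [(s, s + window) for s in starts]
    if out[-1][1] < length:
        out.append((starts[-1] + step, length))  # final truncated window
    return out


@dataclass(frozen=True)
class FragmentGrid:
    protein_windows: tuple[tuple[int, int], ...]
    rna_windows: tuple[tuple[int, int], ...]


def make_grid(
    protein_len: int,
    rna_len: int,
    protein_window: int = DEFAULT_PROTEIN_WINDOW,
    protein_step: int = DEFAULT_PROTEIN_STEP,
    rna_window: int = DEFAULT_RNA_WINDOW,
    rna_step: int = DEFAULT_RNA_STEP,
) -> FragmentGrid:
    return FragmentGrid(
        protein_windows=tuple(_windows(protein_len, protein_window, protein_step)),
        rna_windows=tuple(_windows(rna_len, rna_window, rna_step)),
    )


@dataclass(frozen=True)
class InteractionMap:
    grid: FragmentGrid
    scores: np.ndarray  # (n protein windows, n rna windows)
    per_position_protein: np.ndarray
    per_position_rna: np.ndarray


def _fragment(rec: SequenceRecord, start: int, end: int) -> SequenceRecord:
    return SequenceRecord(
        id=f"{rec.id}:{start + 1}-{end}",
        gene_id=rec.gene_id,
        kind=rec.kind,
        sequence=rec.sequence[start:end],
    )


def interaction_map(
    protein: SequenceRecord,
    rna: SequenceRecord,
    scorer,
    grid: FragmentGrid | None = None,
) -> InteractionMap:
    """Score every protein-window x RNA-window fragment pair."""
    if grid is None:
        grid = make_grid(len(protein), len(rna))
    prot_frags = [_fragment(protein, s, e) for s, e in grid.protein_windows]
    rna_frags = [_fragment(rna, s, e) for s, e in grid.rna_windows]
    if hasattr(scorer, "score_matrix"):
        scores = np.asarray(scorer.score_matrix(prot_frags, rna_frags), dtype=float)
    else:
        scores = np.array(
            [[scorer(p, r) for r in rna_frags] for p in prot_frags], dtype=float
        )
    row_best = scores.max(axis=1)  # best partner score per protein window
    col_best = scores.max(axis=0)
    per_prot = np.full(len(protein), -np.inf)
    for (s, e), v in zip(grid.protein_windows, row_best):
        per_prot[s:e] = np.maximum(per_prot[s:e], v)
    per_rna = np.full(len(rna), -np.inf)
    for (s, e), v in zip(grid.rna_windows, col_best):
        per_rna[s:e] = np.maximum(per_rna[s:e], v)
    return InteractionMap(
        grid=grid,
        scores=scores,
        per_position_protein=per_prot,
        per_position_rna=per_rna,
    )


def _runs_at_or_above(profile: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = profile >= threshold
    out: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(profile)))
    return out


def call_binding_regions(
    imap: InteractionMap, quantile: float = 0.9
) -> dict[str, list[tuple[int, int]]]:
    """Merged maximal runs of per-position profile >= its given quantile.

    A flat profile carries no localization signal: no regions are called.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    out: dict[str, list[tuple[int, int]]] = {}
    for key, profile in (
        ("protein", imap.per_position_protein),
        ("rna", imap.per_position_rna),
    ):
        if np.ptp(profile) == 0.0:
            logger.info("flat %s profile: no binding regions called", key)
            out[key] = []
            continue
        thr = float(np.quantile(profile, quantile))
        out[key] = _runs_at_or_above(profile, thr)
    return out


def write_map(imap: InteractionMap, prefix: str | Path) -> None:
    """Write score matrix and per-position profiles (1-based inclusive)."""
    prefix = Path(prefix)
    cols = [f"rna_{s + 1}_{e}" for s, e in imap.grid.rna_windows]
    idx = [f"prot_{s + 1}_{e}" for s, e in imap.grid.protein_windows]
    pd.DataFrame(imap.scores, index=idx, columns=cols).to_csv(
        prefix.with_suffix(".matrix.tsv"), sep="\t"
    )
    for key, profile in (
        ("protein", imap.per_position_protein),
        ("rna", imap.per_position_rna),
    ):
        pd.DataFrame(
            {"position": np.arange(1, len(profile) + 1), "score": profile}
        ).to_csv(prefix.parent / f"{prefix.name}.{key}_profile.tsv", sep="\t", index=False)


def write_regions_bed(
    regions: list[tuple[int, int]], name: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for start, end in regions:
            fh.write(f"{name}\t{start}\t{end}\n")
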