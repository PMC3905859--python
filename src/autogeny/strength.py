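"""Interaction-strength specificity against matched-length random controls.

The strength of a protein-RNA pair is the percentile of its interaction
propensity within the propensity distribution of random control pairs built
from reference sequences of *exactly* the same lengths (by default 100
random proteins x 100 random RNAs = 10^4 control interactions), so the
measure is independent of molecule lengths.  Ties are handled mid-rank, so a
degenerate constant scorer yields 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import scales
from .sequence_io import GeneCatalog, Kind, SequenceRecord

DEFAULT_N_CONTROL = 100  # per side; 100 x 100 = 10^4 control interactions


@dataclass(frozen=True)
class ReferenceSet:
    proteins: tuple[SequenceRecord, ...]
    rnas: tuple[SequenceRecord, ...]
    seed: int
    composition: Mapping[str, Mapping[str, float]]

    @property
    def n_controls(self) -> int:
        return len(self.proteins) * len(self.rnas)


@dataclass(frozen=True)
class StrengthResult:
    strength: float  # percent, in [0, 100]
    n_controls: int
    control_mean: float
    control_sd: float
    control_min: float
    control_max: float


def uniform_composition(kind: Kind | str) -> dict[str, float]:
    if Kind(kind) == Kind.PROTEIN:
        return {aa: 1.0 / 20.0 for aa in scales.AMINO_ACIDS}
    return {nt: 0.25 for nt in scales.NUCLEOTIDES}


def catalog_composition(catalog: GeneCatalog) -> dict[str, dict[str, float]]:
    """Empirical residue frequencies of the catalog (fallback: uniform)."""
    out: dict[str, dict[str, float]] = {}
    for key, records, alphabet in (
        ("protein", catalog.proteins, scales.AMINO_ACIDS),
        ("rna", catalog.transcripts, scales.NUCLEOTIDES),
    ):
        counts = {c: 0 for c in alphabet}
        total = 0
        for rec in records:
            for c in rec.sequence:
                if c in counts:
                    counts[c] += 1
                    total += 1
        if total == 0:
            out[key] = uniform_composition(
                Kind.PROTEIN if key == "protein" else Kind.TRANSCRIPT
            )
        else:
            out[key] = {c: n / total for c, n in counts.items()}
    return out


def _validate_composition(comp: Mapping[str, float], what: str) -> None:
    total = float(sum(comp.values()))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{what} composition sums to {total!r}, expected 1")


def sample_reference(
    protein_len: int,
    rna_len: int,
    composition: Mapping[str, Mapping[str, float]] | None = None,
    n_prot: int = DEFAULT_N_CONTROL,
    n_rna: int = DEFAULT_N_CONTROL,
    seed: int = 0,
) -> ReferenceSet:
    """Draw i.i.d. reference sequences matching the query lengths.

    The generator is keyed on ``(seed, protein_len, rna_len)`` so results do
    not depend on the order in which length pairs are requested within a run.
    """
    if protein_len < 1 or rna_len < 1:
        raise ValueError("lengths must be >= 1")
    if n_prot < 1 or n_rna < 1:
        raise ValueError("control counts must be >= 1")
    if composition is None:
        composition = {
            "protein": uniform_composition(Kind.PROTEIN),
            "rna": uniform_composition(Kind.TRANSCRIPT),
        }
    _validate_composition(composition["protein"], "protein")
    _validate_composition(composition["rna"], "rna")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(protein_len, rna_len))
    )
    aa, p_aa = zip(*sorted(composition["protein"].items()))
    nt, p_nt = zip(*sorted(composition["rna"].items()))
    p_aa = np.asarray(p_aa) / np.sum(p_aa)
    p_nt = np.asarray(p_nt) / np.sum(p_nt)
    proteins = tuple(
        SequenceRecord(
            id=f"refprot_{i:04d}",
            gene_id=f"refprot_{i:04d}",
            kind=Kind.PROTEIN,
            sequence="".join(rng.choice(aa, size=protein_len, p=p_aa)),
        )
        for i in range(n_prot)
    )
    rnas = tuple(
        SequenceRecord(
            id=f"refrna_{i:04d}",
            gene_id=f"refrna_{i:04d}",
            kind=Kind.TRANSCRIPT,
            sequence="".join(rng.choice(nt, size=rna_len, p=p_nt)),
        )
        for i in range(n_rna)
    )
    return ReferenceSet(
        proteins=proteins, rnas=rnas, seed=seed, composition=composition
    )


def control_propensities(scorer, ref: ReferenceSet) -> np.ndarray:
    if hasattr(scorer, "score_matrix"):
        return np.asarray(
            scorer.score_matrix(list(ref.proteins), list(ref.rnas))
        ).ravel()
    return np.array(
        [scorer(p, r) for p in ref.proteins for r in ref.rnas]
    )


def interaction_strength(
    protein: SequenceRecord,
    rna: SequenceRecord,
    scorer,
    ref: ReferenceSet,
) -> StrengthResult:
    """Mid-rank percentile of the pair's propensity among its controls."""
    for rec in ref.proteins:
        if len(rec) != len(protein):
            raise ValueError("reference protein length does not match query")
    for rec in ref.rnas:
        if len(rec) != len(rna):
            raise ValueError("reference RNA length does not match query")
    pi = float(scorer(protein, rna))
    controls = control_propensities(scorer, ref)
    below = int(np.count_nonzero(controls < pi))
    ties = int(np.count_nonzero(controls == pi))
    strength = 100.0 * (below + 0.5 * ties) / controls.size
    return StrengthResult(
        strength=strength,
        n_controls=int(controls.size),
        control_mean=float(controls.mean()),
        control_sd=float(controls.std(ddof=0)),
        control_min=float(controls.min()),
        control_max=float(controls.max()),
    )


class ReferenceCache:
    """One ReferenceSet per (protein_len, rna_len) within a run."""

    def __init__(
        self,
        composition: Mapping[str, Mapping[str, float]] | None = None,
        n_prot: int = DEFAULT_N_CONTROL,
        n_rna: int = DEFAULT_N_CONTROL,
        seed: int = 0,
    ):
        self.composition = composition
        self.n_prot = n_prot
        self.n_rna = n_rna
        self.seed = seed
        self._cache: dict[tuple[int, int], ReferenceSet] = {}

    def get(self, protein_len: int, rna_len: int) -> ReferenceSet:
        key = (protein_len, rna_len)
        if key not in self._cache:
            self._cache[key] = sample_reference(
                protein_len,
                rna_len,
                composition=self.composition,
                n_prot=self.n_prot,
                n_rna=self.n_rna,
                seed=self.seed,
            )
        return self._cache[key]
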