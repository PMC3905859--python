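"""Sequence-based protein-RNA interaction propensity.

The score is a transparent linear surrogate: per-residue physicochemical
tracks are computed for both molecules (secondary-structure propensities,
hydrogen-bonding capacity and polarity for the protein; Nussinov-style
pairedness and GC content for the RNA), each track is compressed to a fixed
number of discrete-cosine coefficients so sequences of different lengths are
comparable, and the interaction propensity is an affine calibration of a
bilinear form over the two coefficient sets:

    pi = slope * sum_{t,r,k} W[t,r,k] * Cp[t,k] * Cr[r,k] + intercept

The scale is procedure-defined: the default calibration puts random
background pairs at a sample mean of ~16 so that thresholds such as 50, 100
and 150 single out increasingly specific interactions.  The model is *not*
a re-implementation of any trained predictor; externally computed scores can
be plugged in through :func:`load_score_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct

from . import scales
from ._pairing import windowed_pairing_track
from .sequence_io import Kind, SequenceRecord

logger = logging.getLogger(__name__)

PROTEIN_TRACKS = ("helix", "sheet", "hbond", "polar")
RNA_TRACKS = ("pairing", "gc")

_PROTEIN_SCALES = {
    "helix": scales.HELIX,
    "sheet": scales.SHEET,
    "hbond": scales.HBOND,
    "polar": scales.POLAR,
}


@dataclass(frozen=True)
class ResidueProfileSet:
    """Named per-position tracks, all of sequence length."""

    tracks: Mapping[str, np.ndarray]
    length: int

    def __post_init__(self) -> None:
        for name, arr in self.tracks.items():
            if arr.shape != (self.length,):
                raise ValueError(f"track {name!r} has wrong length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"track {name!r} contains non-finite values")


@dataclass(frozen=True)
class PropensityScore:
    pi: float


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-truncated (shorter windows at the ends)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    n = len(x)
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - 1 - half), n - 1) + 1
    return (c[hi] - c[lo]) / (hi - lo)


def _lookup_track(seq: str, scale: Mapping[str, float]) -> np.ndarray:
    mean = scales.scale_mean(scale)
    out = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if aa == "X":
            out[i] = mean
        else:
            try:
                out[i] = scale[aa]
            except KeyError:
                raise ValueError(f"unknown residue {aa!r}") from None
    return out


def protein_profiles(seq: str, window: int = 7) -> ResidueProfileSet:
    """Four smoothed physicochemical tracks from fixed per-residue scales."""
    tracks = {
        name: moving_average(_lookup_track(seq, scale), window)
        for name, scale in _PROTEIN_SCALES.items()
    }
    return ResidueProfileSet(tracks=tracks, length=len(seq))


def rna_profiles(
    seq: str,
    pairing_window: int = 101,
    gc_window: int = 7,
    min_loop: int = 3,
) -> ResidueProfileSet:
    """Pairedness (windowed Nussinov) and windowed GC-fraction tracks."""
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)!r}")
    pairing = windowed_pairing_track(seq, window=pairing_window, min_loop=min_loop)
    gc = moving_average(
        np.array([1.0 if c in "GC" else 0.0 for c in seq]), gc_window
    )
    return ResidueProfileSet(tracks={"pairing": pairing, "gc": gc}, length=len(seq))


def compress_profile(track: np.ndarray, n_coeff: int) -> np.ndarray:
    """First ``n_coeff`` DCT-II coefficients, scaled so c0 equals the mean.

    The scaling makes the representation depend on the *shape* of the track
    rather than its length: a track resampled at finer resolution yields
    (asymptotically) the same coefficients.  If the track is shorter than
    ``n_coeff`` the tail is zero-padded (logged).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 1 or len(track) < 1:
        raise ValueError("track must be a non-empty 1-D array")
    if n_coeff < 1:
        raise ValueError("n_coeff must be >= 1")
    n = len(track)
    coeffs = dct(track, type=2) / (2.0 * n)
    if n_coeff <= n:
        return coeffs[:n_coeff].copy()
    logger.info("track length %d < n_coeff %d: zero-padding tail", n, n_coeff)
    out = np.zeros(n_coeff)
    out[:n] = coeffs
    return out


@dataclass(frozen=True)
class InteractionModel:
    """Bilinear scoring model over compressed profile coefficients."""

    n_coeff: int
    weights: np.ndarray  # (len(protein_tracks), len(rna_tracks), n_coeff)
    slope: float
    intercept: float
    protein_tracks: tuple[str, ...] = PROTEIN_TRACKS
    rna_tracks: tuple[str, ...] = RNA_TRACKS
    smoothing_window: int = 7
    pairing_window: int = 101
    gc_window: int = 7

    def __post_init__(self) -> None:
        expected = (len(self.protein_tracks), len(self.rna_tracks), self.n_coeff)
        if self.weights.shape != expected:
            raise ValueError(f"weights must have shape {expected}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")

    def protein_coefficients(self, seq: str) -> np.ndarray:
        prof = protein_profiles(seq, window=self.smoothing_window)
        return np.stack(
            [compress_profile(prof.tracks[t], self.n_coeff) for t in self.protein_tracks]
        )

    def rna_coefficients(self, seq: str) -> np.ndarray:
        prof = rna_profiles(
            seq, pairing_window=self.pairing_window, gc_window=self.gc_window
        )
        return np.stack(
            [compress_profile(prof.tracks[t], self.n_coeff) for t in self.rna_tracks]
        )

    def raw_score(self, cp: np.ndarray, cr: np.ndarray) -> float:
        return float(np.einsum("tk,rk,trk->", cp, cr, self.weights))

    def calibrate_value(self, raw: float | np.ndarray):
        return self.slope * raw + self.intercept


def interaction_propensity(
    protein: SequenceRecord, rna: SequenceRecord, model: InteractionModel
) -> PropensityScore:
    """Deterministic propensity of one pair under ``model``."""
    if protein.kind != Kind.PROTEIN or rna.kind != Kind.TRANSCRIPT:
        raise ValueError("interaction_propensity expects (protein, transcript)")
    cp = model.protein_coefficients(protein.sequence)
    cr = model.rna_coefficients(rna.sequence)
    return PropensityScore(pi=float(model.calibrate_value(model.raw_score(cp, cr))))


class SurrogateScorer:
    """Callable scorer with per-sequence coefficient caching.

    ``scorer(protein_record, rna_record) -> float`` and a vectorized
    ``score_matrix`` used by the whole-catalog and reference-set paths.
    """

    def __init__(self, model: InteractionModel):
        self.model = model
        self._cp: dict[str, np.ndarray] = {}
        self._cr: dict[str, np.ndarray] = {}

    def protein_coeffs(self, seq: str) -> np.ndarray:
        out = self._cp.get(seq)
        if out is None:
            out = self.model.protein_coefficients(seq)
            self._cp[seq] = out
        return out

    def rna_coeffs(self, seq: str) -> np.ndarray:
        out = self._cr.get(seq)
        if out is None:
            out = self.model.rna_coefficients(seq)
            self._cr[seq] = out
        return out

    def __call__(self, protein: SequenceRecord, rna: SequenceRecord) -> float:
        cp = self.protein_coeffs(protein.sequence)
        cr = self.rna_coeffs(rna.sequence)
        return float(self.model.calibrate_value(self.model.raw_score(cp, cr)))

    def score_matrix(
        self,
        proteins: Sequence[SequenceRecord],
        rnas: Sequence[SequenceRecord],
    ) -> np.ndarray:
        cp = np.stack([self.protein_coeffs(p.sequence) for p in proteins])
        cr = np.stack([self.rna_coeffs(r.sequence) for r in rnas])
        raw = np.einsum("itk,jrk,trk->ij", cp, cr, self.model.weights)
        return self.model.calibrate_value(raw)


class TableScorer:
    """Scorer serving precomputed (protein_id, rna_id) -> propensity lookups."""

    def __init__(self, table: Mapping[tuple[str, str], float]):
        self._table = dict(table)

    def __len__(self) -> int:
        return len(self._table)

    def __call__(self, protein: SequenceRecord, rna: SequenceRecord) -> float:
        return self.query(protein.id, rna.id)

    def query(self, protein_id: str, rna_id: str) -> float:
        try:
            return self._table[(protein_id, rna_id)]
        except KeyError:
            raise KeyError(
                f"no precomputed score for pair ({protein_id!r}, {rna_id!r})"
            ) from None


def load_score_table(path: str | Path) -> TableScorer:
    """Load a TSV of columns protein_id, rna_id, propensity into a scorer."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "rna_id", "propensity"}
    if not required <= set(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    table: dict[tuple[str, str], float] = {}
    for pid, rid, pi in zip(df["protein_id"], df["rna_id"], df["propensity"]):
        key = (str(pid), str(rid))
        pi = float(pi)
        if key in table and table[key] != pi:
            raise ValueError(f"conflicting duplicate rows for pair {key!r}")
        table[key] = pi
    return TableScorer(table)
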