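"""Per-residue intrinsic-disorder scores, disorder fractions and the
case-vs-background comparison for autogenously interacting proteins.

The built-in scorer is a charge/hydropathy surrogate in the FoldIndex
tradition: within a centered window (default 21 residues, edge-truncated)
the normalized Kyte-Doolittle hydropathy and the absolute mean net charge
combine into a foldability index

    f = 2.785 * <H_norm> - |<q>| - 1.151

which is squashed through a logistic so the per-residue score lies in
(0, 1); charged hydrophilic stretches score high, hydrophobic ones low.  It
is deliberately swappable: per-residue scores computed by any external
disorder predictor can be loaded from a TSV and used instead.

A residue is disorder prone when its score is strictly above 0.5, and a
protein's disorder fraction is the fraction of such residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import scales
from .partition import ScoredPair
from .propensity import moving_average
from .sequence_io import PairClass, SequenceRecord

DEFAULT_RESIDUE_THRESHOLD = 0.5
DEFAULT_WINDOW = 21
_FOLD_SLOPE = 2.785
_FOLD_INTERCEPT = 1.151
_LOGISTIC_STEEPNESS = 8.0


@dataclass(frozen=True)
class DisorderProfile:
    scores: np.ndarray
    source: str  # "surrogate" or "external_file"

    def __post_init__(self) -> None:
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("disorder scores must lie in [0, 1]")


@dataclass(frozen=True)
class DisorderComparison:
    ks_statistic: float
    p_value: float
    n_case: int
    n_background: int
    case_mean: float
    background_mean: float
    case_median: float
    background_median: float


def disorder_scores(
    protein: SequenceRecord | str,
    window: int = DEFAULT_WINDOW,
    steepness: float = _LOGISTIC_STEEPNESS,
) -> DisorderProfile:
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    kd_mean = scales.scale_mean(scales.KD_HYDROPATHY)
    q_mean = scales.scale_mean(scales.CHARGE)
    hydro = np.array(
        [scales.KD_HYDROPATHY.get(a, kd_mean) for a in seq]
    )
    charge = np.array([scales.CHARGE.get(a, q_mean) for a in seq])
    h_norm = moving_average((hydro + 4.5) / 9.0, window)
    q_win = moving_average(charge, window)
    fold = _FOLD_SLOPE * h_norm - np.abs(q_win) - _FOLD_INTERCEPT
    score = 1.0 / (1.0 + np.exp(steepness * fold))
    return DisorderProfile(scores=score, source="surrogate")


def load_disorder_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Per-residue score TSV: columns protein_id, position (1-based), score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy(dtype=int)
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{pid}: positions must be 1..L without gaps")
        out[str(pid)] = sub["score"].to_numpy(dtype=float)
    return out


def profile_from_file(
    protein: SequenceRecord, table: Mapping[str, np.ndarray]
) -> DisorderProfile:
    scores = table.get(protein.id)
    if scores is None:
        raise KeyError(f"no external disorder scores for {protein.id!r}")
    if len(scores) != len(protein):
        raise ValueError(
            f"{protein.id}: external scores length {len(scores)} != "
            f"sequence length {len(protein)}"
        )
    return DisorderProfile(scores=np.asarray(scores, dtype=float), source="external_file")


def disorder_fraction(
    profile: DisorderProfile, threshold: float = DEFAULT_RESIDUE_THRESHOLD
) -> float:
    """Fraction of residues with score strictly above the threshold."""
    return float(np.mean(profile.scores > threshold))


def kolmogorov_sf(x: float, n_terms: int = 100) -> float:
    """Survival function of the Kolmogorov distribution, Q(x) = 2 sum_k
    (-1)^(k-1) exp(-2 k^2 x^2)."""
    if x <= 0:
        return 1.0
    k = np.arange(1, n_terms + 1)
    return float(np.clip(2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * x**2)), 0.0, 1.0))


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], method: str = "asymp"
) -> DisorderComparison:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    ``method="asymp"`` evaluates the asymptotic Kolmogorov distribution at
    sqrt(n_eff) * D with effective sample size n_eff = n_a*n_b/(n_a+n_b);
    ``method="exact"`` computes the exact small-sample distribution instead.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    if method == "asymp":
        d = float(stats.ks_2samp(a, b, alternative="two-sided").statistic)
        en = len(a) * len(b) / (len(a) + len(b))
        p_raw = kolmogorov_sf(float(np.sqrt(en)) * d)
    elif method == "exact":
        res = stats.ks_2samp(a, b, alternative="two-sided", method="exact")
        d, p_raw = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(min(max(p_raw, np.finfo(float).tiny), 1.0))
    return DisorderComparison(
        ks_statistic=d,
        p_value=p,
        n_case=len(a),
        n_background=len(b),
        case_mean=float(a.mean()),
        background_mean=float(b.mean()),
        case_median=float(np.median(a)),
        background_median=float(np.median(b)),
    )


def disorder_stratification(
    pairs: Sequence[ScoredPair],
    profiles: Mapping[str, DisorderProfile],
    thresholds: Sequence[float],
    residue_threshold: float = DEFAULT_RESIDUE_THRESHOLD,
    method: str = "asymp",
) -> pd.DataFrame:
    """Disorder of autogenously interacting proteins versus the background.

    For each propensity threshold, the case set is every protein (by id) with
    at least one autogenous pair strictly above the threshold; the background
    is the full set of profiled proteins.  Rows with fewer than two case
    proteins carry no test (flagged).
    """
    for p in pairs:
        if p.pair_class == PairClass.AUTOGENOUS and p.protein_id not in profiles:
            raise KeyError(f"no disorder profile for protein {p.protein_id!r}")
    fractions = {
        pid: disorder_fraction(prof, residue_threshold)
        for pid, prof in profiles.items()
    }
    background = np.array(sorted(fractions.values()))
    rows = []
    for thr in thresholds:
        case_ids = sorted(
            {
                p.protein_id
                for p in pairs
                if p.pair_class == PairClass.AUTOGENOUS and p.pi > thr
            }
        )
        case = np.array([fractions[c] for c in case_ids])
        row: dict[str, object] = {"threshold": thr, "n_case": len(case)}
        if len(case) < 2:
            row.update(
                ks_statistic=np.nan,
                p_value=np.nan,
                n_background=len(background),
                case_mean=np.nan,
                background_mean=float(background.mean()),
                case_median=np.nan,
                background_median=float(np.median(background)),
                tested=False,
            )
        else:
            cmp_ = ks_two_sample(case, background, method=method)
            row.update(
                ks_statistic=cmp_.ks_statistic,
                p_value=cmp_.p_value,
                n_background=cmp_.n_background,
                case_mean=cmp_.case_mean,
                background_mean=cmp_.background_mean,
                case_median=cmp_.case_median,
                background_median=cmp_.background_median,
                tested=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
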