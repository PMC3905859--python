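"""Windowed Nussinov maximal-pairing surrogate for RNA pairedness.

For each window of the transcript the classic Nussinov dynamic program
(maximal number of non-crossing AU/GC/GU pairs, minimum hairpin loop length
enforced) is solved and one optimal structure is traced back with a fixed,
deterministic tie-break order.  A position's pairedness value is the mean of
its paired/unpaired indicator over every window covering it, hence lies in
[0, 1].  This keeps the track sharp at structure boundaries (hairpin arms
high, loops low) while remaining deterministic and cheap compared with full
partition-function folding.

The inner DP is JIT-compiled with numba when available; the pure-Python
fallback runs the identical integer arithmetic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


# nucleotide codes: A=0, C=1, G=2, U=3, N=4 (N never pairs)
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"illegal nucleotide {exc.args[0]!r}") from exc


@njit(cache=True)
def _paired_mask(codes, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    out = np.zeros(n, dtype=np.uint8)
    if n < min_loop + 2:
        return out
    table = np.zeros((n, n), dtype=np.int32)
    # can_pair[a, b]: AU, GC, GU (symmetric); N (4) pairs with nothing
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = table[i + 1, j]
            if table[i, j - 1] > best:
                best = table[i, j - 1]
            a = codes[i]
            b = codes[j]
            pair = (
                (a == 0 and b == 3)
                or (a == 3 and b == 0)
                or (a == 1 and b == 2)
                or (a == 2 and b == 1)
                or (a == 2 and b == 3)
                or (a == 3 and b == 2)
            )
            if pair and table[i + 1, j - 1] + 1 > best:
                best = table[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = table[i, k] + table[k + 1, j]
                if v > best:
                    best = v
            table[i, j] = best
    # deterministic traceback: unpair j, pair (i, j), then bifurcate
    stack_i = np.empty(2 * n + 4, dtype=np.int64)
    stack_j = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if j - i <= min_loop:
            continue
        if table[i, j] == table[i, j - 1]:
            stack_i[top] = i
            stack_j[top] = j - 1
            top += 1
            continue
        a = codes[i]
        b = codes[j]
        pair = (
            (a == 0 and b == 3)
            or (a == 3 and b == 0)
            or (a == 1 and b == 2)
            or (a == 2 and b == 1)
            or (a == 2 and b == 3)
            or (a == 3 and b == 2)
        )
        if pair and table[i, j] == table[i + 1, j - 1] + 1:
            out[i] = 1
            out[j] = 1
            stack_i[top] = i + 1
            stack_j[top] = j - 1
            top += 1
            continue
        if table[i, j] == table[i + 1, j]:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
            continue
        for k in range(i + 1, j):
            if table[i, k] + table[k + 1, j] == table[i, j]:
                stack_i[top] = i
                stack_j[top] = k
                top += 1
                stack_i[top] = k + 1
                stack_j[top] = j
                top += 1
                break
    return out


def nussinov_pair_count(seq: str, min_loop: int = 3) -> int:
    """Maximal number of non-crossing pairs (AU/GC/GU) in ``seq``."""
    mask = _paired_mask(encode(seq), min_loop)
    return int(mask.sum()) // 2


def paired_indicator(seq: str, min_loop: int = 3) -> np.ndarray:
    """0/1 per-position paired indicator of one maximal-pairing structure."""
    return _paired_mask(encode(seq), min_loop).astype(float)


def windowed_pairing_track(
    seq: str, window: int = 101, stride: int | None = None, min_loop: int = 3
) -> np.ndarray:
    """Per-position pairedness in [0, 1], averaged over covering windows."""
    n = len(seq)
    codes = encode(seq)
    if stride is None:
        stride = max(1, window // 2)
    if n <= window:
        return _paired_mask(codes, min_loop).astype(float)
    starts = list(range(0, n - window + 1, stride))
    if starts[-1] + window < n:
        starts.append(n - window)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for s in starts:
        mask = _paired_mask(codes[s : s + window], min_loop)
        acc[s : s + window] += mask
        cnt[s : s + window] += 1.0
    return acc / np.maximum(cnt, 1.0)
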