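"""Shared statistical primitives: empirical p-values, circular rotations, robust scaling.

These are the low-level building blocks used by the permutation-null and
decoding machinery. They are deliberately small and heavily tested.
"""

from __future__ import annotations

import numpy as np

#: tolerance used when comparing a null statistic against the observed one,
#: so that exact ties (e.g. an all-zero trace where every null delta equals
#: the observed delta) count as "at least as extreme" instead of producing p=0
TIE_TOL = 1e-12


def empirical_p(null: np.ndarray, observed: float, tail: str = "greater",
                add_one: bool = True, tol: float = TIE_TOL) -> float:
    """Empirical p-value of ``observed`` against a permutation ``null``.

    With ``add_one`` (default) the permutation add-one correction
    (k + 1) / (n + 1) is applied so that p >= 1/(n+1); with
    ``add_one=False`` the raw proportion k / n is returned.
    Ties within ``tol`` count as at-least-as-extreme.
    """
    null = np.asarray(null, dtype=float)
    if null.ndim != 1 or null.size == 0:
        raise ValueError("null distribution must be a non-empty 1-d array")
    if tail == "greater":
        k = int(np.sum(null >= observed - tol))
    elif tail == "less":
        k = int(np.sum(null <= observed + tol))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    n = null.size
    if add_one:
        return (k + 1) / (n + 1)
    return k / n


def window_sums_circular(trace: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """Sums of ``trace[s:s+length]`` with wrap-around, for an array of starts.

    Used to evaluate circular-rotation null statistics without materialising
    each rotated trace: rotating the trace by ``s`` and reading a fixed window
    is the same as reading the window at ``start - s (mod N)`` in the original.
    O(1) per window via a doubled cumulative sum.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if length > n:
        raise ValueError("window longer than trace")
    cs = np.concatenate([[0.0], np.cumsum(np.concatenate([trace, trace]))])
    starts = np.asarray(starts) % n
    return cs[starts + length] - cs[starts]


def robust_z(x: np.ndarray) -> np.ndarray:
    """Robust z-scores using median and MAD (scaled to s.d. for a normal).

    Degenerate MAD = 0 falls back to the ordinary s.d.; if that is also 0
    the trace is constant and a zero array is returned.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = mad * 1.4826
    if scale == 0:
        scale = np.std(x)
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def derive_seed(seed: int, *salts: int) -> int:
    """Derive a reproducible 31-bit child seed from a parent seed and salts."""
    ss = np.random.SeedSequence([int(seed), *[int(s) for s in salts]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
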