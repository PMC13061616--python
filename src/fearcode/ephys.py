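"""Single-unit spike-train statistics.

Pip-responsiveness classification (peri-stimulus 100-ms bins z-scored to
the 500-ms pre-pip baseline, responsive when any of the 5 post-pip bins
exceeds the two-tailed P < 0.01 critical value z = 2.58), the
freezing-modulation index (rate_freeze - rate_move)/(rate_freeze +
rate_move), and Pearson chi-squared tests on responder proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpikeTrain",
    "PipSchedule",
    "EpochSet",
    "UnitResponse",
    "critical_z",
    "pip_responsiveness",
    "freezing_index",
    "proportion_test",
]


@dataclass
class SpikeTrain:
    unit_id: int | str
    times: np.ndarray  # s, sorted
    tagged: bool = False  # optogenetically identified projection neuron

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(np.diff(self.times) < 0) or self.times[0] < 0):
            raise ValueError("spike times must be sorted and non-negative")


@dataclass
class PipSchedule:
    """Onsets of the 500-ms auditory pips composing each CS train."""

    onsets: np.ndarray
    pip_duration: float = 0.5

    def __post_init__(self) -> None:
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) < self.pip_duration):
            raise ValueError("pips overlap")


@dataclass
class EpochSet:
    """Freezing and movement intervals; the two must not overlap."""

    freeze: np.ndarray  # (n, 2) onset/offset s
    move: np.ndarray

    def __post_init__(self) -> None:
        self.freeze = np.asarray(self.freeze, dtype=float).reshape(-1, 2)
        self.move = np.asarray(self.move, dtype=float).reshape(-1, 2)
        for name, iv in (("freeze", self.freeze), ("move", self.move)):
            if iv.size and np.any(iv[:, 1] < iv[:, 0]):
                raise ValueError(f"{name} intervals must have offset >= onset")
        for f in self.freeze:
            for m in self.move:
                if max(f[0], m[0]) < min(f[1], m[1]):
                    raise ValueError("freeze and move intervals overlap")

    @staticmethod
    def _total(iv: np.ndarray) -> float:
        return float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0


@dataclass
class UnitResponse:
    """Per-unit pip-response z-profile and classification."""

    unit_id: int | str
    z: np.ndarray  # one value per 100-ms post-pip bin
    responsive: bool
    degenerate: bool = False
    freezing_index: float | None = None
    extras: dict = field(default_factory=dict)


def critical_z(p: float = 0.01, two_tailed: bool = True, decimals: int = 2) -> float:
    """Standard-normal critical value for the responsiveness criterion.

    The conventional per-bin threshold is the two-tailed P < 0.01 quantile,
    Phi^-1(1 - p/2), rounded to ``decimals`` (2.58 at p = 0.01).
    """
    q = 1 - p / 2 if two_tailed else 1 - p
    return float(np.round(stats.norm.ppf(q), decimals))


def pip_responsiveness(st: SpikeTrain, pips: PipSchedule, bin_s: float = 0.1,
                       baseline_s: float = 0.5, response_s: float = 0.5,
                       z_crit: float = 2.58, two_sided: bool = False,
                       baseline_stat: str = "sem") -> UnitResponse:
    """Classify a unit as pip-responsive from its peri-pip spike counts.

    Spike counts in 100-ms bins (half-open ``[t, t+bin)``; a spike on a
    boundary belongs to the later bin) are averaged across all pips. Each
    of the 5 post-pip bins is z-scored against the across-pip baseline
    (the 500-ms pre-pip period): z = (bin value - baseline mean) /
    (s.d. of the baseline mean value). With ``baseline_stat='sem'``
    (default) the denominator is the null standard error of the
    bin-minus-baseline difference,
    ``sd(per-pip baseline counts)/sqrt(n_pips) * sqrt(1 + 1/n_base_bins)``,
    under which z is asymptotically standard normal for a stationary unit;
    ``'per_bin_sd'`` instead uses the s.d. of the across-pip-averaged
    baseline bin values (anticonservative with few baseline bins).

    Responsive iff any post-pip bin exceeds ``z_crit`` (excitation only by
    default; ``two_sided=True`` tests |z|). A unit whose baseline spread is
    zero (e.g. silent) is degenerate and never responsive.
    """
    onsets = pips.onsets
    if onsets.size == 0:
        raise ValueError("no pips in schedule")
    n_base = int(round(baseline_s / bin_s))
    n_resp = int(round(response_s / bin_s))
    edges_rel = bin_s * np.arange(-n_base, n_resp + 1)

    counts = np.empty((onsets.size, n_base + n_resp))
    for pi, t in enumerate(onsets):
        counts[pi] = np.histogram(st.times, bins=t + edges_rel)[0]
    base = counts[:, :n_base]          # per-pip baseline bin counts
    post_mean = counts[:, n_base:].mean(axis=0)

    base_mean = base.mean()
    if baseline_stat == "sem":
        spread = (base.std(ddof=1) / np.sqrt(onsets.size)
                  * np.sqrt(1 + 1 / n_base))
    elif baseline_stat == "per_bin_sd":
        spread = base.mean(axis=0).std(ddof=1)
    else:
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")
    if not np.isfinite(spread) or spread == 0:
        z = np.zeros(n_resp)
        return UnitResponse(st.unit_id, z, responsive=False, degenerate=True)
    z = (post_mean - base_mean) / spread
    hits = np.abs(z) > z_crit if two_sided else z > z_crit
    return UnitResponse(st.unit_id, z, responsive=bool(hits.any()))


def freezing_index(st: SpikeTrain, epochs: EpochSet) -> float:
    """Freezing-modulation index (rate_freeze - rate_move)/(rate_freeze + rate_move).

    Rates are spikes-in-epoch / total epoch duration. Bounded in [-1, 1];
    NaN (reported as missing) when both rates are zero.
    """
    t_f, t_m = EpochSet._total(epochs.freeze), EpochSet._total(epochs.move)
    if t_f <= 0 and t_m <= 0:
        raise ValueError("no freezing or movement time")

    def _count(iv: np.ndarray) -> int:
        return int(sum(np.searchsorted(st.times, b) - np.searchsorted(st.times, a)
                       for a, b in iv))

    r_f = _count(epochs.freeze) / t_f if t_f > 0 else 0.0
    r_m = _count(epochs.move) / t_m if t_m > 0 else 0.0
    if r_f + r_m == 0:
        return float("nan")
    return (r_f - r_m) / (r_f + r_m)


def proportion_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test (df = 1, no continuity correction) on a 2x2
    count table of responder proportions between groups."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("proportion_test expects a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; expected counts undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
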