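"""Bulk fibre-photometry peri-event analysis.

A single fluorescence channel (population Ca2+ signal collected through an
optical fibre) is analysed around behavioural events: traces are extracted
in peri-event windows, z-scored to the pre-event baseline, summarised by
bootstrap confidence bands and trapezoidal AUC, and screened for Ca2+
transients. Movement-aligned averages normalised to the session mean are
also provided.

Conventions (pinned, see docs/methods.md):

* time 0 is the event onset; windows are half-open ``[-pre, post)`` and the
  sample at t=0 belongs to the post-window;
* "s.d." always means the sample standard deviation (n-1 denominator);
* bootstrap bands use the percentile method on the trial-mean trace and a
  bin is flagged significant only when its CI excludes the null level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._stats import robust_z

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "EventSchedule",
    "PeriEventMatrix",
    "SignificanceBand",
    "extract_peri_event",
    "zscore_to_baseline",
    "bootstrap_band",
    "auc",
    "count_transients",
    "align_to_movement",
]


@dataclass
class TimeSeries:
    """One fluorescence (or behaviour) channel sampled at a fixed rate."""

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-d")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries contains non-finite values")

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (floor to the containing sample)."""
        return int(round((t - self.t0) * self.sampling_rate))


@dataclass
class EventSchedule:
    """Labelled events/epochs: (label, onset_s, duration_s) rows.

    Labels follow the convention ``CS_onset``, ``US_onset``, ``move_onset``,
    ``move_offset``, ``freeze`` ... but arbitrary labels are accepted.
    """

    table: pd.DataFrame

    REQUIRED = ("label", "onset_s", "duration_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"EventSchedule missing columns {missing}")
        if (self.table["duration_s"] < 0).any():
            raise ValueError("event durations must be >= 0")
        self.table = self.table.sort_values("onset_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_events(cls, labels, onsets, durations=None) -> "EventSchedule":
        onsets = np.asarray(onsets, dtype=float)
        if durations is None:
            durations = np.zeros_like(onsets)
        if np.isscalar(labels):
            labels = [labels] * onsets.size
        return cls(pd.DataFrame({"label": list(labels), "onset_s": onsets,
                                 "duration_s": np.asarray(durations, dtype=float)}))

    def onsets(self, label: str) -> np.ndarray:
        return self.table.loc[self.table["label"] == label, "onset_s"].to_numpy()

    def intervals(self, label: str) -> np.ndarray:
        """(n, 2) array of (onset, offset) for a given label."""
        sub = self.table[self.table["label"] == label]
        return np.column_stack([sub["onset_s"].to_numpy(),
                                (sub["onset_s"] + sub["duration_s"]).to_numpy()])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventSchedule":
        return cls(pd.read_csv(path))


@dataclass
class PeriEventMatrix:
    """Trials x samples matrix of activity time-locked to an event onset."""

    data: np.ndarray  # (n_trials, n_samples)
    pre_s: float
    post_s: float
    sampling_rate: float
    event_times: np.ndarray | None = None
    baseline_mean: np.ndarray | None = None  # per retained trial
    baseline_sd: np.ndarray | None = None
    excluded_trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        expect = int(round((self.pre_s + self.post_s) * self.sampling_rate))
        if self.data.shape[1] != expect:
            raise ValueError(
                f"sample count {self.data.shape[1]} != round((pre+post)*rate) = {expect}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time of each sample relative to event onset; t=0 starts the post-window."""
        return -self.pre_s + np.arange(self.data.shape[1]) / self.sampling_rate

    @property
    def pre_n(self) -> int:
        return int(round(self.pre_s * self.sampling_rate))

    def pre_slice(self) -> slice:
        return slice(0, self.pre_n)

    def post_slice(self) -> slice:
        return slice(self.pre_n, self.data.shape[1])


@dataclass
class SignificanceBand:
    """Per-bin bootstrap CI of the trial-mean trace plus significance flags."""

    bin_times: np.ndarray  # bin centres, s relative to onset
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    flagged: np.ndarray  # bool, CI excludes the null level
    n_boot: int
    alpha: float
    bin_s: float
    null_level: float = 0.0


def extract_peri_event(ts: TimeSeries, sched: EventSchedule, label: str,
                       pre_s: float, post_s: float) -> PeriEventMatrix:
    """Cut one row per event of ``label``, time-locked at onset.

    Raises if any selected event lacks ``pre_s`` of history or ``post_s`` of
    future within the session, naming the offending event.
    """
    onsets = sched.onsets(label)
    if onsets.size == 0:
        raise ValueError(f"no events with label {label!r}")
    pre_n = int(round(pre_s * ts.sampling_rate))
    post_n = int(round(post_s * ts.sampling_rate))
    rows = []
    for t in onsets:
        i = ts.index_of(t)
        if i - pre_n < 0 or i + post_n > ts.values.size:
            raise ValueError(
                f"event {label!r} at t={t:g}s too close to session edge for "
                f"window [-{pre_s}, {post_s})")
        rows.append(ts.values[i - pre_n:i + post_n])
    return PeriEventMatrix(np.array(rows), pre_s, post_s, ts.sampling_rate,
                           event_times=onsets)


def zscore_to_baseline(pem: PeriEventMatrix) -> PeriEventMatrix:
    """Z-score each trial to its own pre-event window.

    z = (x - mean(pre)) / sd(pre) with the sample s.d. (n-1). Trials whose
    pre-window s.d. is zero carry no usable baseline and are excluded (and
    logged), never silently propagated as inf/nan.
    """
    if pem.pre_n < 2:
        raise ValueError("pre-window must contain at least 2 samples")
    pre = pem.data[:, pem.pre_slice()]
    mu = pre.mean(axis=1)
    sd = pre.std(axis=1, ddof=1)
    valid = sd > 0
    excluded = list(np.flatnonzero(~valid))
    if excluded:
        logger.warning("excluding %d trial(s) with zero baseline s.d.: %s",
                       len(excluded), excluded)
    z = (pem.data[valid] - mu[valid, None]) / sd[valid, None]
    ev = pem.event_times[valid] if pem.event_times is not None else None
    return PeriEventMatrix(z, pem.pre_s, pem.post_s, pem.sampling_rate,
                           event_times=ev, baseline_mean=mu[valid],
                           baseline_sd=sd[valid], excluded_trials=excluded)


def bootstrap_band(pem: PeriEventMatrix, n_boot: int = 1000, alpha: float = 0.05,
                   bin_s: float = 0.010, null_level: float = 0.0,
                   rng: np.random.Generator | int | None = None) -> SignificanceBand:
    """Percentile-bootstrap confidence band of the trial-mean trace.

    Trials are resampled with replacement ``n_boot`` times; the CI per time
    bin is the (alpha/2, 1-alpha/2) percentile envelope of the binned
    bootstrap means, and a bin is flagged significant iff its CI excludes
    ``null_level`` (default 0, i.e. the peri-event baseline after z-scoring).
    """
    if pem.n_trials < 2:
        raise ValueError("bootstrap_band requires at least 2 trials")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CIs will be unstable", stacklevel=2)
    rng = np.random.default_rng(rng)

    samples_per_bin = max(1, int(round(bin_s * pem.sampling_rate)))
    n_bins = pem.data.shape[1] // samples_per_bin
    used = n_bins * samples_per_bin
    binned = pem.data[:, :used].reshape(pem.n_trials, n_bins, samples_per_bin).mean(axis=2)

    idx = rng.integers(0, pem.n_trials, size=(n_boot, pem.n_trials))
    boot_means = binned[idx].mean(axis=1)  # (n_boot, n_bins)
    lo = np.percentile(boot_means, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    flagged = (lo > null_level) | (hi < null_level)

    centres = (-pem.pre_s + (np.arange(n_bins) + 0.5) * samples_per_bin / pem.sampling_rate)
    return SignificanceBand(centres, binned.mean(axis=0), lo, hi, flagged,
                            n_boot=n_boot, alpha=alpha, bin_s=bin_s,
                            null_level=null_level)


def auc(pem: PeriEventMatrix, sub_window: tuple[float, float]) -> np.ndarray:
    """Per-trial trapezoidal AUC (z*s) over ``sub_window`` (s, relative to onset).

    The sub-window must lie inside the peri-event window and span at least
    two samples.
    """
    lo, hi = sub_window
    if lo < -pem.pre_s - 1e-9 or hi > pem.post_s + 1e-9 or hi <= lo:
        raise ValueError("sub_window outside the peri-event window")
    t = pem.times
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("sub_window spans fewer than 2 samples")
    return np.trapezoid(pem.data[:, mask], t[mask], axis=1)


def count_transients(ts: TimeSeries, threshold: float, min_separation_s: float,
                     relative_to_baseline: bool = True):
    """Count Ca2+ transients as separated supra-threshold local maxima.

    By default the threshold is in robust z units of the whole session
    (median/MAD scaling) — a deterministic replacement for visual threshold
    tuning — which makes detection invariant to additive offsets. With
    ``relative_to_baseline=False`` the threshold applies to raw trace values.

    Returns ``(count, event_times, cumulative)`` where ``cumulative`` is the
    cumulative transient count evaluated at every sample.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_separation_s <= 0:
        raise ValueError("min_separation_s must be positive")
    x = robust_z(ts.values) if relative_to_baseline else ts.values
    distance = max(1, int(round(min_separation_s * ts.sampling_rate)))
    peaks, _ = find_peaks(x, height=threshold, distance=distance)
    event_times = ts.t0 + peaks / ts.sampling_rate
    cumulative = np.searchsorted(peaks, np.arange(ts.values.size), side="right")
    return peaks.size, event_times, cumulative


def align_to_movement(ts: TimeSeries, sched: EventSchedule, pre_s: float, post_s: float):
    """Trial-averaged traces around movement onsets and offsets, normalised
    to the session-average fluorescence.

    Only epochs with a full peri-window inside the session qualify; raises if
    none do for either alignment point.
    """
    session_mean = ts.values.mean()
    if session_mean == 0:
        raise ValueError("session mean is zero; cannot normalise")
    out = {}
    for key, label in (("onset", "move_onset"), ("offset", "move_offset")):
        onsets = sched.onsets(label)
        pre_n = int(round(pre_s * ts.sampling_rate))
        post_n = int(round(post_s * ts.sampling_rate))
        rows = [ts.values[i - pre_n:i + post_n]
                for i in (ts.index_of(t) for t in onsets)
                if i - pre_n >= 0 and i + post_n <= ts.values.size]
        if not rows:
            raise ValueError(f"no qualifying movement {key}s for window "
                             f"[-{pre_s}, {post_s})")
        out[key] = np.mean(rows, axis=0) / session_mean
    return out["onset"], out["offset"]
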