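"""Cellular-resolution Ca2+ imaging statistics.

Handles cell x time dF/F matrices from one- or two-photon imaging:
baseline normalisation (session-median or 25-frame moving-average F0),
event exclusion filters, classification of CS-modulated cells by a
circular-rotation permutation test or by paired t-test on event activity,
cross-stage responder categories, and spatial topography of responder
subsets.

The circular-rotation null is the workhorse: a cell's whole-session trace
is rotated by a random offset, which preserves its autocorrelation but
destroys alignment to the CS schedule, and the post-minus-pre activity
delta is recomputed under each rotation. Empirical p-values use the
permutation add-one correction (k+1)/(n+1) by default so p >= 1/(n_rot+1);
the raw proportion k/n is available via ``add_one=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TIE_TOL, window_sums_circular
from .photometry import EventSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "CellMatrix",
    "ModulationResult",
    "CrossStageResult",
    "dff",
    "filter_events",
    "classify_modulation_circular",
    "classify_event_modulation_ttest",
    "cross_stage",
    "centroid_distances",
]

CATEGORIES = ("positive", "negative", "none")
CROSS_STAGE_LABELS = ("increasing", "decreasing", "sustained", "nonresponsive")


@dataclass
class CellMatrix:
    """Cells x samples dF/F with trial schedule and optional centroids."""

    data: np.ndarray  # (n_cells, n_samples)
    sampling_rate: float
    schedule: EventSchedule | None = None
    cell_ids: np.ndarray | None = None
    centroids: np.ndarray | None = None  # (n_cells, 2), arbitrary units
    stage: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CellMatrix contains non-finite values")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.data.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.size != self.data.shape[0]:
                raise ValueError("cell_ids length must equal cell count")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.data.shape[0], 2):
                raise ValueError("centroids must be (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def dff(F: np.ndarray, mode: str = "moving_average", window_frames: int = 25) -> np.ndarray:
    """Relative fluorescence change dF/F0 = (F - F0)/F0.

    ``mode='moving_average'`` uses a centred ``window_frames``-frame moving
    average as F0 (reflect-padded at the edges); ``mode='session_median'``
    uses the median of the whole trace. Works on 1-d traces or cell x time
    arrays (rowwise).
    """
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        return _dff_1d(F, mode, window_frames)
    return np.vstack([_dff_1d(row, mode, window_frames) for row in F])


def _dff_1d(F: np.ndarray, mode: str, window_frames: int) -> np.ndarray:
    if mode == "session_median":
        f0 = np.full_like(F, np.median(F))
    elif mode == "moving_average":
        if window_frames > F.size:
            raise ValueError("moving-average window longer than trace")
        half = window_frames // 2
        padded = np.pad(F, half, mode="reflect")
        kernel = np.ones(window_frames) / window_frames
        f0 = np.convolve(padded, kernel, mode="valid")[:F.size]
    else:
        raise ValueError(f"unknown dff mode {mode!r}")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 is non-positive; dF/F undefined")
    return (F - f0) / f0


def filter_events(events: pd.DataFrame, max_dff: float = 7.0,
                  max_duration_frames: int = 60) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude imaging events with implausible amplitude or duration.

    Events with peak dF/F0 above ``max_dff`` or duration above
    ``max_duration_frames`` frames are dropped. Expects columns
    ``max_dff`` and ``duration_frames``. Returns ``(retained, excluded)``
    where ``excluded`` carries a ``reason`` column.
    """
    for col in ("max_dff", "duration_frames"):
        if col not in events.columns:
            raise ValueError(f"events table missing column {col!r}")
    too_big = events["max_dff"] > max_dff
    too_long = events["duration_frames"] > max_duration_frames
    excluded = events[too_big | too_long].copy()
    reasons = []
    for big, long_ in zip(too_big[too_big | too_long], too_long[too_big | too_long]):
        parts = (["amplitude"] if big else []) + (["duration"] if long_ else [])
        reasons.append("+".join(parts))
    excluded["reason"] = reasons
    retained = events[~(too_big | too_long)].copy()
    if len(excluded):
        logger.info("filter_events excluded %d/%d events", len(excluded), len(events))
    return retained, excluded


@dataclass
class ModulationResult:
    """Per-cell CS-modulation calls with their permutation nulls."""

    table: pd.DataFrame  # columns: cell_id, delta, p_pos, p_neg, category, stage
    null_deltas: np.ndarray | None = None  # (n_cells, n_rot)
    params: dict = field(default_factory=dict)

    @property
    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()

    def fraction(self, category: str) -> float:
        return float(np.mean(self.categories == category))

    def ids(self, category: str) -> np.ndarray:
        return self.table.loc[self.table["category"] == category, "cell_id"].to_numpy()

    def nominal_false_call_rate(self) -> float:
        """Exact per-tail false-call probability of the permutation test on
        null data: the add-one p takes values (k+1)/(n_rot+1), so the call
        rate at level alpha is (number of attainable p below alpha)/(n_rot+1)."""
        n_rot, alpha = self.params["n_rot"], self.params["alpha"]
        m = int(np.ceil(alpha * (n_rot + 1))) - 1
        return max(m, 0) / (n_rot + 1)

    def recovered_fraction(self, category: str = "positive", correct: bool = True) -> float:
        """Estimate the true fraction of modulated cells in ``category``.

        The raw call rate r overestimates the true fraction f because null
        cells are called at the test's nominal rate a: E[r] = f + (1-f)*a
        when the modulated cells are reliably detected. The standard
        mixture-fraction correction (r - a)/(1 - a) removes that bias;
        ``correct=False`` returns the raw call rate.
        """
        r = self.fraction(category)
        if not correct:
            return r
        a = self.nominal_false_call_rate()
        return max((r - a) / (1 - a), 0.0)


def classify_modulation_circular(cm: CellMatrix, label: str = "CS_onset",
                                 pre_s: float = 5.0, post_s: float = 5.0,
                                 n_rot: int = 500, alpha: float = 0.05,
                                 add_one: bool = True,
                                 rng: np.random.Generator | int | None = None) -> ModulationResult:
    """Classify each cell as positively / negatively CS-modulated or none.

    The observed statistic per cell is the post-minus-pre mean-activity
    delta averaged across CS trials. The null is the same statistic after
    circularly rotating the cell's whole-session trace by a random offset,
    ``n_rot`` times (offsets drawn uniformly over positions keeping the
    windows in-session). Two one-sided tests at ``alpha`` each:
    positive when p+ < alpha, negative when p- < alpha.

    Constant traces are degenerate and always called ``none``.
    """
    if cm.schedule is None:
        raise ValueError("CellMatrix has no event schedule")
    onsets = cm.schedule.onsets(label)
    if onsets.size == 0:
        raise ValueError(f"no events with label {label!r}")
    rate = cm.sampling_rate
    pre_n = int(round(pre_s * rate))
    post_n = int(round(post_s * rate))
    n = cm.n_samples
    if n <= pre_n + post_n:
        raise ValueError("trace too short for the peri-event windows")
    onset_idx = np.round(onsets * rate).astype(int)
    if np.any(onset_idx - pre_n < 0) or np.any(onset_idx + post_n > n):
        raise ValueError("a CS event lies too close to the session edge")

    rng = np.random.default_rng(rng)
    lo, hi = pre_n, n - post_n  # valid rotation offsets
    rows = []
    nulls = np.empty((cm.n_cells, n_rot))
    for ci in range(cm.n_cells):
        trace = cm.data[ci]
        obs = _mean_delta(trace, onset_idx, pre_n, post_n)
        offsets = rng.integers(lo, hi, size=n_rot)
        # rotating trace by +s == reading windows at (onset - s) mod n
        shifted = (onset_idx[None, :] - offsets[:, None]) % n
        pre_sums = window_sums_circular(trace, (shifted - pre_n) % n, pre_n)
        post_sums = window_sums_circular(trace, shifted, post_n)
        null = (post_sums / post_n - pre_sums / pre_n).mean(axis=1)
        nulls[ci] = null

        if np.ptp(trace) == 0:  # constant trace: degenerate, never significant
            p_pos = p_neg = 1.0
        else:
            k_pos = int(np.sum(null >= obs - TIE_TOL))
            k_neg = int(np.sum(null <= obs + TIE_TOL))
            if add_one:
                p_pos = (k_pos + 1) / (n_rot + 1)
                p_neg = (k_neg + 1) / (n_rot + 1)
            else:
                p_pos, p_neg = k_pos / n_rot, k_neg / n_rot
        if p_pos < alpha:
            category = "positive"
        elif p_neg < alpha:
            category = "negative"
        else:
            category = "none"
        rows.append((cm.cell_ids[ci], obs, p_pos, p_neg, category, cm.stage))

    table = pd.DataFrame(rows, columns=["cell_id", "delta", "p_pos", "p_neg",
                                        "category", "stage"])
    return ModulationResult(table, null_deltas=nulls,
                            params={"label": label, "pre_s": pre_s, "post_s": post_s,
                                    "n_rot": n_rot, "alpha": alpha, "add_one": add_one})


def _mean_delta(trace: np.ndarray, onset_idx: np.ndarray, pre_n: int, post_n: int) -> float:
    pre = np.mean([trace[i - pre_n:i].mean() for i in onset_idx])
    post = np.mean([trace[i:i + post_n].mean() for i in onset_idx])
    return float(post - pre)


def classify_event_modulation_ttest(pre_means: np.ndarray, post_means: np.ndarray,
                                    alpha: float = 0.05, event_id=0,
                                    stage: str = "") -> pd.Series:
    """Paired t-test call for one imaging event's peri-CS activity.

    ``pre_means``/``post_means`` are per-trial mean activities in the pre-
    and post-CS halves of the 20-s peri-CS window. The call is ``positive``
    when the one-sided post > pre test rejects at ``alpha``. Fewer than two
    trials or zero difference variance is degenerate and yields ``none``.
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have matching shapes")
    degenerate = pre.size < 2 or np.allclose(np.var(post - pre), 0)
    if degenerate:
        return pd.Series({"event_id": event_id, "delta": float(np.mean(post - pre)) if pre.size else np.nan,
                          "p": np.nan, "category": "none", "degenerate": True,
                          "stage": stage})
    t, p = stats.ttest_rel(post, pre, alternative="greater")
    return pd.Series({"event_id": event_id, "delta": float(np.mean(post - pre)),
                      "p": float(p), "category": "positive" if p < alpha else "none",
                      "degenerate": False, "stage": stage})


@dataclass
class CrossStageResult:
    """Cross-stage responder categories for co-registered cells/events."""

    table: pd.DataFrame  # id, category_a, category_b, label
    dropped_ids: list = field(default_factory=list)

    def fraction(self, label: str) -> float:
        return float(np.mean(self.table["label"].to_numpy() == label))


def cross_stage(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                id_col: str = "cell_id") -> CrossStageResult:
    """Assign cross-stage categories to cells co-registered in two stages.

    Given per-stage binary modulation categories, a cell is
    ``increasing`` ("conditionally CS excited") when it gains a positive
    call from stage A to B, ``decreasing`` when it loses one, ``sustained``
    when positive in both, and ``nonresponsive`` when modulated in neither.
    Negative calls are handled symmetrically (a gained negative call counts
    as increasing inhibition -> ``increasing`` with sign recorded in the
    per-stage columns). Ids missing from either stage are excluded and
    logged.
    """
    a = calls_a.set_index(id_col)["category"]
    b = calls_b.set_index(id_col)["category"]
    common = a.index.intersection(b.index)
    dropped = sorted(set(a.index).symmetric_difference(b.index))
    if dropped:
        logger.info("cross_stage dropping %d unmatched ids", len(dropped))
    rows = []
    for cid in common:
        rows.append((cid, a[cid], b[cid], _cross_stage_label(a[cid], b[cid])))
    table = pd.DataFrame(rows, columns=["cell_id", "category_a", "category_b", "label"])
    return CrossStageResult(table, dropped_ids=dropped)


def _cross_stage_label(cat_a: str, cat_b: str) -> str:
    """Pure function mapping a per-stage category pair to a cross-stage label."""
    mod_a, mod_b = cat_a != "none", cat_b != "none"
    if not mod_a and mod_b:
        return "increasing"
    if mod_a and not mod_b:
        return "decreasing"
    if mod_a and mod_b:
        # same-sign persistence is sustained; a sign flip is a category change
        return "sustained" if cat_a == cat_b else "decreasing"
    return "nonresponsive"


def centroid_distances(centroids: np.ndarray) -> np.ndarray:
    """Euclidean distance of each cell to the centroid of the subset.

    Used to quantify spatial clustering of CS-related cells within the
    field of view (arbitrary units).
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.size == 0:
        raise ValueError("empty cell subset")
    centre = pts.mean(axis=0)
    return np.linalg.norm(pts - centre, axis=1)
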