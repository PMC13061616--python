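"""Population decoding and ensemble-information analyses.

Three decoding analyses are implemented, all built on an L2-penalised
logistic classifier scored by held-out F1 against circular-rotation or
label-permutation shuffle nulls:

* ``decode_cs_astro`` — CS presentation decoded from astrocyte event
  activity, with pseudo post-CS windows constructed from non-contiguous
  0.5-s intervals and trial-grouped five-fold cross-validation;
* ``decode_group`` — treatment-group identity decoded per animal from
  summary features of CS-related neuronal activity with
  leave-one-mouse-out folds;
* ``decode_cs_vs_popsize`` — CS decoding as a function of ensemble size
  (sampling without replacement, one-neuron increments), summarised by a
  Michaelis-Menten-form saturating fit y = b*n/(a+n) whose initial slope
  b/a estimates the information contributed per neuron.

PCA population trajectories with a BH-corrected per-bin permutation test,
k-means clustering of peri-CS response shapes, and the one-tailed Pearson
correlation between decoder coefficients and freezing complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from statsmodels.stats.multitest import multipletests

from ._stats import empirical_p, derive_seed
from .imaging import CellMatrix

__all__ = [
    "DecodingResult",
    "SizeCurve",
    "SaturatingModel",
    "SaturatingFitResults",
    "TrajectoryResult",
    "MouseSession",
    "construct_cs_windows",
    "decode_cs_astro",
    "decode_group",
    "decode_cs_vs_popsize",
    "fit_saturating",
    "pca_trajectories",
    "kmeans_responses",
    "coef_freezing_correlation",
]

GROUP_FEATURES = ("mean_pos", "mean_neg", "mean_none", "sd_all_5s", "pc1", "pc2", "pc3")


# --------------------------------------------------------------------------- #
# results containers
# --------------------------------------------------------------------------- #

@dataclass
class DecodingResult:
    """Observed cross-validated F1 with its shuffle-null distribution."""

    observed_f1: float
    fold_scores: np.ndarray
    null_f1: np.ndarray
    p_value: float
    cv: str
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def null_band(self) -> tuple[float, float]:
        """2.5-97.5 percentile band of the shuffle null."""
        return (float(np.percentile(self.null_f1, 2.5)),
                float(np.percentile(self.null_f1, 97.5)))

    def summary(self) -> str:
        lo, hi = self.null_band
        return (f"observed F1 = {self.observed_f1:.3f}; shuffle null "
                f"[{lo:.3f}, {hi:.3f}] (n={self.null_f1.size}); p = {self.p_value:.4g} "
                f"({self.cv})")


@dataclass
class SizeCurve:
    """Held-out F1 as a function of ensemble size, with a matched shuffle curve."""

    sizes: np.ndarray
    scores: np.ndarray          # (n_sizes, n_reps)
    shuffle_scores: np.ndarray  # (n_sizes, n_shuffle_reps)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")

    @property
    def means(self) -> np.ndarray:
        return self.scores.mean(axis=1)

    @property
    def shuffle_means(self) -> np.ndarray:
        return self.shuffle_scores.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean_f1": self.means,
                             "shuffle_mean_f1": self.shuffle_means})


# --------------------------------------------------------------------------- #
# shared classifier plumbing
# --------------------------------------------------------------------------- #

def _classifier() -> LogisticRegression:
    # L2 penalty at the conventional default strength (C = 1); both are the
    # sklearn defaults, pinned explicitly via C
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)

def _fold_assignment(n_trials: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold labels for trials after a seeded shuffle."""
    order = rng.permutation(n_trials)
    folds = np.empty(n_trials, dtype=int)
    folds[order] = np.arange(n_trials) % n_folds
    return folds

def _grouped_cv_f1(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   folds: np.ndarray) -> np.ndarray:
    """Mean F1 per fold, training on out-of-fold trials. Degenerate folds
    (single-class training set) are skipped."""
    scores = []
    trial_fold = folds  # per trial
    sample_fold = trial_fold[groups]
    for f in np.unique(trial_fold):
        train, test = sample_fold != f, sample_fold == f
        if np.unique(y[train]).size < 2 or not test.any():
            continue
        clf = _classifier().fit(X[train], y[train])
        scores.append(f1_score(y[test], clf.predict(X[test]), zero_division=0))
    if not scores:
        raise ValueError("all cross-validation folds were degenerate")
    return np.asarray(scores)


# --------------------------------------------------------------------------- #
# CS decoding from astrocyte events
# --------------------------------------------------------------------------- #

def construct_cs_windows(n_post_samples: int, sampling_rate: float,
                         n_intervals: int = 10, interval_s: float = 0.5,
                         rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample a pseudo post-CS window of ``n_intervals`` disjoint intervals.

    Returns sorted sample indices (relative to the post-window start) of
    ``n_intervals`` non-contiguous ``interval_s``-long stretches randomly
    placed in the post window — used to equate pre- and post-CS window
    lengths for decoding. Deterministic given the RNG state.
    """
    rng = np.random.default_rng(rng)
    L = max(1, int(round(interval_s * sampling_rate)))
    k = n_intervals
    if k * L > n_post_samples:
        raise ValueError(
            f"cannot place {k} disjoint {interval_s}-s intervals "
            f"({k * L} samples) in a {n_post_samples}-sample window")
    # bijection between k disjoint length-L intervals and k distinct slots
    slots = np.sort(rng.choice(n_post_samples - k * (L - 1), size=k, replace=False))
    starts = slots + np.arange(k) * (L - 1)
    return (starts[:, None] + np.arange(L)[None, :]).ravel()


def _pre_post_features(raster: np.ndarray, onset_idx: np.ndarray, pre_n: int,
                       post_rel_idx: np.ndarray):
    """Per-trial (pre, post) feature vectors: mean activity per row (cell/event).

    Returns X (2*n_trials, n_rows), y (0 pre / 1 post), trial group ids.
    """
    Xs, ys, gs = [], [], []
    for ti, i in enumerate(onset_idx):
        Xs.append(raster[:, i - pre_n:i].mean(axis=1))
        ys.append(0)
        gs.append(ti)
        Xs.append(raster[:, i + post_rel_idx].mean(axis=1))
        ys.append(1)
        gs.append(ti)
    return np.asarray(Xs), np.asarray(ys), np.asarray(gs)


def decode_cs_astro(raster: np.ndarray, sampling_rate: float, onsets_s: np.ndarray,
                    pre_s: float = 5.0, post_window_s: float = 30.0,
                    n_constructions: int = 1000, n_folds: int = 5,
                    n_shuffle: int = 1000, n_intervals: int = 10,
                    interval_s: float = 0.5, seed: int = 0) -> DecodingResult:
    """Decode CS presentation from astrocyte event activity.

    ``raster`` is events x time activity. Per CS trial the classifier sees
    one 5-s pre-CS sample and one pseudo 5-s post-CS sample constructed
    from ``n_intervals`` random non-contiguous ``interval_s`` intervals of
    the 30-s post window; construction is repeated ``n_constructions``
    times and the observed score is the mean F1 over constructions x
    trial-grouped folds. The null repeats the procedure on circularly
    rotated activity ``n_shuffle`` times; the empirical p uses the add-one
    correction.
    """
    raster = np.atleast_2d(np.asarray(raster, dtype=float))
    onsets_s = np.asarray(onsets_s, dtype=float)
    n_trials = onsets_s.size
    if n_trials < n_folds:
        raise ValueError(f"need >= {n_folds} CS trials for {n_folds}-fold CV, "
                         f"got {n_trials}")
    rate = sampling_rate
    pre_n = int(round(pre_s * rate))
    post_n = int(round(post_window_s * rate))
    n = raster.shape[1]
    onset_idx = np.round(onsets_s * rate).astype(int)
    if np.any(onset_idx - pre_n < 0) or np.any(onset_idx + post_n > n):
        raise ValueError("a CS trial lies too close to the session edge")

    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n_trials, n_folds, rng)

    def _score(data: np.ndarray, n_cons: int, rng_: np.random.Generator) -> np.ndarray:
        per_cons = []
        for _ in range(n_cons):
            rel = construct_cs_windows(post_n, rate, n_intervals, interval_s, rng_)
            X, y, g = _pre_post_features(data, onset_idx, pre_n, rel)
            per_cons.append(_grouped_cv_f1(X, y, g, folds))
        return np.concatenate(per_cons)

    fold_scores = _score(raster, n_constructions, rng)
    observed = float(fold_scores.mean())

    null = np.empty(n_shuffle)
    # the rotation must exceed the full peri-event span: smaller shifts leave
    # a trial's response inside its own (long) post window and contaminate
    # the null with self-realignments
    span = pre_n + post_n
    lo, hi = span, n - span
    if lo >= hi:
        raise ValueError("session too short to rotate past the peri-event span")
    for s in range(n_shuffle):
        offset = int(rng.integers(lo, hi))
        rotated = np.roll(raster, offset, axis=1)
        null[s] = _score(rotated, 1, rng).mean()
    p = empirical_p(null, observed, tail="greater")
    return DecodingResult(observed, fold_scores, null, p,
                          cv=f"trial-grouped {n_folds}-fold", seed=seed,
                          extras={"n_constructions": n_constructions,
                                  "n_trials": n_trials})


# --------------------------------------------------------------------------- #
# treatment-group decoding per animal
# --------------------------------------------------------------------------- #

@dataclass
class MouseSession:
    """One animal's imaging session plus its treatment-group label."""

    matrix: CellMatrix
    group: str
    categories: np.ndarray | None = None  # per-cell modulation category


def _peri_cs_trial_average(cm: CellMatrix, label: str, pre_s: float,
                           post_s: float) -> np.ndarray:
    """Session-z-scored, trial-averaged peri-CS activity, neurons x samples."""
    mu = cm.data.mean(axis=1, keepdims=True)
    sd = cm.data.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (cm.data - mu) / sd
    rate = cm.sampling_rate
    pre_n, post_n = int(round(pre_s * rate)), int(round(post_s * rate))
    onset_idx = np.round(cm.schedule.onsets(label) * rate).astype(int)
    chunks = [z[:, i - pre_n:i + post_n] for i in onset_idx]
    return np.mean(chunks, axis=0)


def _mouse_feature(session: MouseSession, feature: str, label: str, pre_s: float,
                   post_s: float, n_subsample: int, n_draws: int,
                   rng: np.random.Generator) -> np.ndarray:
    avg = _peri_cs_trial_average(session.matrix, label, pre_s, post_s)
    pre_n = int(round(pre_s * session.matrix.sampling_rate))
    post = avg[:, pre_n:]

    if feature in ("mean_pos", "mean_neg", "mean_none"):
        if session.categories is None:
            raise ValueError(f"feature {feature!r} needs per-cell categories")
        want = {"mean_pos": "positive", "mean_neg": "negative", "mean_none": "none"}[feature]
        pool = np.flatnonzero(np.asarray(session.categories) == want)
        if pool.size == 0:
            raise ValueError(f"no cells of category {want!r} in mouse session")
        draws = [post[rng.choice(pool, size=n_subsample, replace=True)].mean(axis=0)
                 for _ in range(n_draws)]
        return np.mean(draws, axis=0)
    if feature == "sd_all_5s":
        half = post.shape[1] // 2
        return post[:, :half].std(axis=0, ddof=1)
    if feature in ("pc1", "pc2", "pc3"):
        k = int(feature[-1]) - 1
        centred = avg - avg.mean(axis=1, keepdims=True)  # mean-normalised per neuron
        pca = PCA(n_components=min(3, *centred.shape), random_state=0)
        pca.fit(centred)
        comp = pca.components_[k]
        return comp * np.sign(comp[np.argmax(np.abs(comp))])  # fix sign
    raise ValueError(f"unknown feature {feature!r}; choose from {GROUP_FEATURES}")


def decode_group(sessions: list[MouseSession], feature: str, label: str = "CS_onset",
                 pre_s: float = 5.0, post_s: float = 5.0, n_subsample: int = 5,
                 n_draws: int = 100, n_shuffle: int = 100,
                 seed: int = 0) -> DecodingResult:
    """Decode treatment-group identity across animals from one neural feature.

    Each mouse contributes one feature vector (equated across mice by
    averaging ``n_draws`` subsamples of ``n_subsample`` neurons drawn with
    replacement where the feature is a category mean). Folds are
    leave-one-mouse-out; the null permutes group labels across mice.
    """
    groups = sorted({s.group for s in sessions})
    if len(groups) != 2:
        raise ValueError("decode_group requires exactly 2 groups")
    for g in groups:
        if sum(s.group == g for s in sessions) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 mice")
    rng = np.random.default_rng(seed)
    X = np.asarray([_mouse_feature(s, feature, label, pre_s, post_s,
                                   n_subsample, n_draws, rng) for s in sessions])
    y = np.asarray([groups.index(s.group) for s in sessions])

    def _lomo_f1(y_: np.ndarray) -> np.ndarray:
        scores = np.empty(len(y_))
        for i in range(len(y_)):
            train = np.arange(len(y_)) != i
            clf = _classifier().fit(X[train], y_[train])
            scores[i] = f1_score(y_[[i]], clf.predict(X[[i]]), zero_division=1)
        return scores

    fold_scores = _lomo_f1(y)
    observed = float(fold_scores.mean())
    null = np.array([_lomo_f1(rng.permutation(y)).mean() for _ in range(n_shuffle)])
    p = empirical_p(null, observed, tail="greater")
    return DecodingResult(observed, fold_scores, null, p,
                          cv=f"leave-one-mouse-out ({len(y)} folds)", seed=seed,
                          extras={"feature": feature})


# --------------------------------------------------------------------------- #
# CS decoding versus population size + saturating fit
# --------------------------------------------------------------------------- #

def decode_cs_vs_popsize(cm: CellMatrix, label: str = "CS_onset", pre_s: float = 5.0,
                         post_s: float = 5.0, sizes=None, n_reps: int = 50,
                         n_shuffle_reps: int = 50, n_folds: int = 5,
                         seed: int = 0) -> SizeCurve:
    """Held-out F1 for CS decoding at increasing ensemble sizes.

    At each size, ``n_reps`` random neuron subsets (without replacement)
    are decoded with trial-grouped CV; the matched shuffle curve repeats
    this on circularly rotated activity. Sizes exceeding the available
    neuron count are truncated with a warning.
    """
    if sizes is None:
        sizes = np.arange(2, 101)
    sizes = np.asarray(sizes)
    if sizes.max() > cm.n_cells:
        warnings.warn(f"max size {sizes.max()} exceeds available neurons "
                      f"({cm.n_cells}); truncating", stacklevel=2)
        sizes = sizes[sizes <= cm.n_cells]
    rate = cm.sampling_rate
    pre_n, post_n = int(round(pre_s * rate)), int(round(post_s * rate))
    onset_idx = np.round(cm.schedule.onsets(label) * rate).astype(int)
    n_trials = onset_idx.size
    if n_trials < n_folds:
        raise ValueError(f"need >= {n_folds} trials")
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n_trials, n_folds, rng)
    rel = np.arange(post_n)

    X_full, y, g = _pre_post_features(cm.data, onset_idx, pre_n, rel)

    def _curve(X: np.ndarray, reps: int) -> np.ndarray:
        out = np.empty((sizes.size, reps))
        for si, size in enumerate(sizes):
            for r in range(reps):
                cols = rng.choice(X.shape[1], size=size, replace=False)
                out[si, r] = _grouped_cv_f1(X[:, cols], y, g, folds).mean()
        return out

    scores = _curve(X_full, n_reps)

    span = pre_n + post_n  # rotate past the peri-event span (see decode_cs_astro)
    lo, hi = span, cm.n_samples - span
    shuffle = np.empty((sizes.size, n_shuffle_reps))
    for r in range(n_shuffle_reps):
        rotated = np.roll(cm.data, int(rng.integers(lo, hi)), axis=1)
        Xr, _, _ = _pre_post_features(rotated, onset_idx, pre_n, rel)
        for si, size in enumerate(sizes):
            cols = rng.choice(Xr.shape[1], size=size, replace=False)
            shuffle[si, r] = _grouped_cv_f1(Xr[:, cols], y, g, folds).mean()
    return SizeCurve(sizes, scores, shuffle)


def _saturating(n, a, b):
    return b * n / (a + n)


class SaturatingModel:
    """Michaelis-Menten-form model of decoder performance vs ensemble size.

    y = b*n / (a + n), where b is the asymptotic performance at infinite
    population size and a the saturation rate (the size at which half the
    asymptote is reached). The initial slope b/a is reported as the
    information contributed per neuron.
    """

    BOUNDS = ((1e-6, 1e-12), (1e4, 1.0))

    def __init__(self, sizes: np.ndarray, scores: np.ndarray):
        self.sizes = np.asarray(sizes, dtype=float)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            scores = scores[:, None]
        if scores.shape[0] != self.sizes.size:
            raise ValueError("scores must be (n_sizes, n_reps)")
        if self.sizes.size < 3:
            raise ValueError("need >= 3 distinct sizes")
        self.scores = scores

    @classmethod
    def from_curve(cls, curve: SizeCurve) -> "SaturatingModel":
        return cls(curve.sizes, curve.scores)

    def _fit_once(self, y_by_size: np.ndarray, p0=None) -> tuple[float, float]:
        n = np.repeat(self.sizes, y_by_size.shape[1])
        y = y_by_size.ravel()
        if p0 is None:
            p0 = (float(np.median(self.sizes)), float(np.clip(y.max(), 1e-6, 1.0)))
        lo, hi = self.BOUNDS
        try:
            popt, _ = curve_fit(_saturating, n, y, p0=p0,
                                bounds=(list(lo), list(hi)), maxfev=10000)
            return float(popt[0]), float(popt[1])
        except RuntimeError:
            pass
        # retry from a grid of initialisations before giving up
        for a0 in np.geomspace(0.1, 1000, 9):
            for b0 in (0.25, 0.5, 0.75, 1.0):
                try:
                    popt, _ = curve_fit(_saturating, n, y, p0=(a0, b0),
                                        bounds=(list(lo), list(hi)), maxfev=10000)
                    return float(popt[0]), float(popt[1])
                except RuntimeError:
                    continue
        raise RuntimeError("saturating fit failed to converge from all initialisations")

    def fit(self, n_boot: int = 1000,
            rng: np.random.Generator | int | None = None) -> "SaturatingFitResults":
        """Least-squares fit plus bootstrap over per-size replicate scores."""
        a, b = self._fit_once(self.scores)
        boot = np.empty((0, 3))
        if n_boot > 0:
            rng = np.random.default_rng(rng)
            n_reps = self.scores.shape[1]
            draws = []
            for _ in range(n_boot):
                cols = rng.integers(0, n_reps, size=(self.sizes.size, n_reps))
                resampled = np.take_along_axis(self.scores, cols, axis=1)
                ab, bb = self._fit_once(resampled, p0=(a, b))
                draws.append((ab, bb, bb / ab))
            boot = np.asarray(draws)
        return SaturatingFitResults(self, a, b, boot)


@dataclass
class SaturatingFitResults:
    """Fitted saturation rate a, asymptote b, and per-neuron information b/a."""

    model: SaturatingModel
    a: float
    b: float
    bootstrap: np.ndarray  # (n_boot, 3): a, b, info_rate

    @property
    def info_rate(self) -> float:
        """Initial slope b/a: performance gained per neuron at small n."""
        return self.b / self.a

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.bootstrap.size == 0:
            raise ValueError("fit was run without bootstrap draws")
        q = np.percentile(self.bootstrap, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame(q.T, index=["a", "b", "info_rate"], columns=["low", "high"])

    def bootstrap_median(self) -> pd.Series:
        if self.bootstrap.size == 0:
            raise ValueError("fit was run without bootstrap draws")
        return pd.Series(np.median(self.bootstrap, axis=0), index=["a", "b", "info_rate"])

    def predict(self, n: np.ndarray) -> np.ndarray:
        return _saturating(np.asarray(n, dtype=float), self.a, self.b)

    def summary(self) -> str:
        lines = ["Saturating fit  y = b*n/(a+n)",
                 f"  a (saturation rate, neurons): {self.a:.4g}",
                 f"  b (asymptotic F1):            {self.b:.4g}",
                 f"  b/a (info per neuron):        {self.info_rate:.4g}"]
        if self.bootstrap.size:
            ci = self.conf_int()
            lines.append(f"  info rate 95% CI:             "
                         f"[{ci.loc['info_rate', 'low']:.4g}, "
                         f"{ci.loc['info_rate', 'high']:.4g}] "
                         f"({self.bootstrap.shape[0]} bootstrap refits)")
        return "\n".join(lines)


def fit_saturating(curve: SizeCurve | tuple, n_boot: int = 1000,
                   rng: np.random.Generator | int | None = None) -> SaturatingFitResults:
    """Convenience wrapper: fit the saturating model to a size curve."""
    model = (SaturatingModel.from_curve(curve) if isinstance(curve, SizeCurve)
             else SaturatingModel(*curve))
    return model.fit(n_boot=n_boot, rng=rng)


# --------------------------------------------------------------------------- #
# PCA trajectories, clustering, coefficient-freezing correlation
# --------------------------------------------------------------------------- #

@dataclass
class TrajectoryResult:
    """Per-group PCA of peri-CS population activity plus a per-bin group test."""

    variance_explained: dict  # group -> variance fraction per PC
    pc1: dict                 # group -> PC1 trajectory over time bins
    p_values: np.ndarray | None
    flagged: np.ndarray | None
    alpha: float = 0.05


def _group_pc1(mat: np.ndarray, n_components: int):
    centred = mat - mat.mean(axis=1, keepdims=True)
    pca = PCA(n_components=min(n_components, *centred.shape), random_state=0)
    pca.fit(centred)
    comp = pca.components_[0]
    # orient PC1 to correlate positively with the mean population trace
    if comp @ centred.mean(axis=0) < 0:
        comp = -comp
    return pca.explained_variance_ratio_, comp


def pca_trajectories(group_matrices: dict[str, np.ndarray], n_perm: int = 1000,
                     alpha: float = 0.05, n_components: int = 10,
                     seed: int = 0) -> TrajectoryResult:
    """PCA of trial-averaged peri-CS activity per group, with a per-time-bin
    permutation test on the PC1 trajectory difference.

    Each group's matrix is neurons x time (already trial-averaged and
    z-scored); rows are mean-normalised before PCA. With two groups the
    per-bin statistic is |PC1_A(t) - PC1_B(t)|; the null permutes neuron
    group membership, and flags are Benjamini-Hochberg corrected at
    ``alpha``. A single group yields variance/trajectory only.
    """
    groups = list(group_matrices)
    var, pc1 = {}, {}
    for gname, mat in group_matrices.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            raise ValueError("need >= 2 neurons and >= 2 time bins per group")
        var[gname], pc1[gname] = _group_pc1(mat, n_components)
    if len(groups) == 1:
        return TrajectoryResult(var, pc1, None, None, alpha)
    if len(groups) != 2:
        raise ValueError("trajectory comparison supports exactly 2 groups")

    ga, gb = groups
    obs = np.abs(pc1[ga] - pc1[gb])
    pooled = np.vstack([group_matrices[ga], group_matrices[gb]])
    n_a = group_matrices[ga].shape[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(obs.size)
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        _, c_a = _group_pc1(pooled[perm[:n_a]], n_components)
        _, c_b = _group_pc1(pooled[perm[n_a:]], n_components)
        exceed += np.abs(c_a - c_b) >= obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    flagged = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return TrajectoryResult(var, pc1, p, flagged, alpha)


def kmeans_responses(responses: np.ndarray, k: int = 4, seed: int = 0,
                     n_init: int = 10):
    """k-means clustering of peri-CS response shapes (one row per neuron).

    Deterministic given ``seed``; the best of ``n_init`` restarts by
    inertia is returned as ``(labels, centroids)``.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if responses.shape[0] < k:
        raise ValueError(f"need >= {k} neurons for k={k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(responses)
    return labels, km.cluster_centers_


def coef_freezing_correlation(coefs: np.ndarray, freezing: np.ndarray,
                              mouse_ids: np.ndarray | None = None,
                              alternative: str = "greater") -> tuple[float, float]:
    """One-tailed Pearson correlation between decoder coefficients and freezing.

    With ``mouse_ids`` the per-neuron ``coefs`` are first averaged by mouse
    and correlated against the per-mouse ``freezing`` percentages (ordered
    by sorted mouse id); otherwise ``coefs`` are taken as already per-mouse.
    """
    coefs = np.asarray(coefs, dtype=float)
    freezing = np.asarray(freezing, dtype=float)
    if mouse_ids is not None:
        s = pd.Series(coefs).groupby(np.asarray(mouse_ids)).mean()
        coefs = s.sort_index().to_numpy()
    if coefs.size != freezing.size:
        raise ValueError("coefficient and freezing vectors differ in length")
    if coefs.size < 3:
        raise ValueError("need >= 3 mice")
    if np.std(coefs) == 0 or np.std(freezing) == 0:
        raise ValueError("zero variance in coefficients or freezing")
    res = stats.pearsonr(coefs, freezing, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
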