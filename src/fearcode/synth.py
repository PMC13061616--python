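"""Synthetic recording-session generator with known ground truth.

Emulates the three recording modalities consumed by the analysis modules —
bulk photometry traces, cell x time dF/F matrices, and spike trains with
pip schedules and freezing/movement epochs — so that every downstream
statistic can be validated by parameter recovery without external data.

What is emulated: stimulus-locked Ca2+ transients (double-exponential
kernels, slower for astrocytes than neurons) on noisy baselines;
heterogeneous responder subpopulations (excited / inhibited /
non-responsive in configured fractions); group-dependent effect sizes
(a multiplicative gain standing in for chemogenetic manipulation); and
piecewise-homogeneous Poisson spiking with epoch-dependent rates and
optional pip-locked boosts. What is NOT emulated: raw movies, biophysical
Ca2+ dynamics, or behaviour video — the generator's distributional choices
are stand-ins, not measurements.

Determinism: one RNG stream per session keyed by ``seed``; per-cell/unit
sub-streams are spawned deterministically, so identical (seed, config)
gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import EpochSet, PipSchedule, SpikeTrain
from .imaging import CellMatrix
from .photometry import EventSchedule, TimeSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_photometry_session",
    "generate_cell_session",
    "generate_spike_session",
    "save_cell_session",
    "load_cell_session",
]

# double-exponential kernel time constants (s); astrocyte responses are
# slower to peak and longer lasting than neuronal ones
NEURON_TAUS = (0.5, 2.0)
ASTRO_TAUS = (2.0, 8.0)


@dataclass
class SynthConfig:
    """All knobs of a synthetic session. Defaults mirror the emulated
    protocol: 30-s CS presentations, 3 trials with a 75-s inter-CS
    interval, 10-Hz imaging, modest dF/F noise."""

    seed: int = 0
    sampling_rate: float = 10.0           # Hz
    session_length: float | None = None   # s; derived from the schedule if None
    n_trials: int = 3
    cs_duration: float = 30.0             # s
    inter_cs_interval: float = 75.0       # mean s between CS offset and next onset
    inter_cs_jitter: float = 15.0         # ITIs ~ U(interval - j, interval + j);
                                          # variable ITIs (60-90 s by default) keep
                                          # a single circular rotation from
                                          # re-aligning every trial at once
    first_onset: float = 60.0             # s; must clear the peri-event pre-window
    edge_margin: float = 5.0              # peri-event pre-window guard (s)
    n_cells: int = 100                    # cells / events / units, per modality
    fraction_positive: float = 0.0
    fraction_negative: float = 0.0
    effect_size: float = 2.0              # transient amplitude, in noise-s.d. units
    noise_sd: float = 0.1                 # dF/F units
    group_gain: float = 1.0               # scales effect size (e.g. CNO vs vehicle)
    tau_rise: float = NEURON_TAUS[0]
    tau_decay: float = NEURON_TAUS[1]
    ar1: float = 0.0                      # AR(1) noise coefficient; 0 = iid
    with_centroids: bool = False
    # spiking
    baseline_rate: float = 5.0            # Hz
    freeze_rate: float | None = None      # Hz during freezing (None -> baseline)
    move_rate: float | None = None        # Hz during movement (None -> baseline)
    pip_boost: float = 0.0                # Hz added in the first post-pip bin
    pips_per_cs: int = 20                 # 500-ms pips at 1 Hz -> 20-s train
    pip_period: float = 1.0               # s
    pip_duration: float = 0.5             # s
    pip_boost_window: float = 0.1         # s, first post-pip bin
    # movement/freezing epochs: alternating blocks of this length (s); None = none
    epoch_block_s: float | None = None
    movement_effect: float = 0.0          # additive dF/F during movement epochs

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fraction_positive < 0 or self.fraction_negative < 0:
            raise ValueError("fractions must be non-negative")
        if self.fraction_positive + self.fraction_negative > 1:
            raise ValueError("fraction_positive + fraction_negative must be <= 1")
        if self.first_onset < self.edge_margin:
            raise ValueError(
                f"first CS onset {self.first_onset}s lies inside the "
                f"{self.edge_margin}s peri-event pre-window")

    def cs_onsets(self) -> np.ndarray:
        """Deterministic CS onset times; ITIs drawn from a seed-derived stream."""
        if self.inter_cs_jitter < 0 or self.inter_cs_jitter > self.inter_cs_interval:
            raise ValueError("inter_cs_jitter must be in [0, inter_cs_interval]")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xC5]))
        itis = self.inter_cs_interval + rng.uniform(
            -self.inter_cs_jitter, self.inter_cs_jitter, size=max(self.n_trials - 1, 0))
        return self.first_onset + np.concatenate(
            [[0.0], np.cumsum(self.cs_duration + itis)])

    def resolved_length(self) -> float:
        needed = self.cs_onsets()[-1] + self.cs_duration + self.inter_cs_interval
        if self.session_length is None:
            return needed
        if self.session_length < needed:
            raise ValueError(
                f"session_length {self.session_length}s too short for "
                f"{self.n_trials} trials (needs >= {needed:g}s)")
        return self.session_length


@dataclass
class GroundTruth:
    """True per-cell/unit parameters used to generate a session."""

    category: np.ndarray | None = None    # positive | negative | none
    amplitude: np.ndarray | None = None   # dF/F peak of the injected transient
    rates: dict = field(default_factory=dict)
    group: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "category": None if self.category is None else list(map(str, self.category)),
            "amplitude": None if self.amplitude is None else [float(a) for a in self.amplitude],
            "rates": self.rates,
            "group": self.group,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _double_exp_kernel(rate: float, tau_rise: float, tau_decay: float,
                       length_s: float | None = None) -> np.ndarray:
    """Unit-peak double-exponential transient kernel."""
    if length_s is None:
        length_s = 6 * tau_decay
    t = np.arange(0, length_s, 1 / rate)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def _noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    eps = rng.normal(0, sd, size=n)
    if ar1 == 0:
        return eps
    out = np.empty(n)
    # stationary AR(1) with marginal s.d. = sd
    out[0] = eps[0]
    innov_sd = np.sqrt(1 - ar1**2)
    for i in range(1, n):
        out[i] = ar1 * out[i - 1] + innov_sd * eps[i]
    return out


def _add_kernel(trace: np.ndarray, idx: int, kernel: np.ndarray, amp: float) -> None:
    stop = min(idx + kernel.size, trace.size)
    trace[idx:stop] += amp * kernel[: stop - idx]


def _movement_schedule(cfg: SynthConfig, length: float) -> list[tuple[str, float, float]]:
    """Alternating move/freeze blocks covering the session."""
    rows = []
    t, moving = 0.0, True
    while t + cfg.epoch_block_s <= length:
        label = "move" if moving else "freeze"
        rows.append((label, t, cfg.epoch_block_s))
        moving = not moving
        t += cfg.epoch_block_s
    return rows


def generate_photometry_session(cfg: SynthConfig,
                                taus: tuple[float, float] | None = None):
    """Bulk fluorescence trace with CS-locked transients.

    Returns ``(TimeSeries, EventSchedule, GroundTruth)``. The trace is
    Gaussian (optionally AR(1)) baseline noise plus a double-exponential
    transient of amplitude ``effect_size * noise_sd * group_gain`` at each
    CS onset. Movement epochs (and ``move_onset``/``move_offset`` markers)
    are included when ``epoch_block_s`` is set.
    """
    length = cfg.resolved_length()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = int(round(length * cfg.sampling_rate))
    trace = _noise(rng, n, cfg.noise_sd, cfg.ar1)

    tr, td = taus if taus is not None else (cfg.tau_rise, cfg.tau_decay)
    kernel = _double_exp_kernel(cfg.sampling_rate, tr, td)
    amp = cfg.effect_size * cfg.noise_sd * cfg.group_gain
    onsets = cfg.cs_onsets()
    rows = [("CS_onset", t, cfg.cs_duration) for t in onsets]
    for t in onsets:
        _add_kernel(trace, int(round(t * cfg.sampling_rate)), kernel, amp)

    if cfg.epoch_block_s is not None:
        for label, t0, dur in _movement_schedule(cfg, length):
            if label == "move":
                rows.append(("move_onset", t0, 0.0))
                rows.append(("move_offset", t0 + dur, 0.0))
                if cfg.movement_effect:
                    i0 = int(round(t0 * cfg.sampling_rate))
                    i1 = int(round((t0 + dur) * cfg.sampling_rate))
                    trace[i0:i1] += cfg.movement_effect
            rows.append((label, t0, dur))

    sched = EventSchedule(pd.DataFrame(rows, columns=["label", "onset_s", "duration_s"]))
    truth = GroundTruth(amplitude=np.array([amp]), group="A" if cfg.group_gain else "B")
    return TimeSeries(trace, cfg.sampling_rate), sched, truth


def _assign_categories(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact-count category assignment: round(fraction * n) cells per
    responder class, positions shuffled. Exact counts make downstream
    fraction-recovery measure classifier error rather than sampling noise."""
    n_pos = int(round(cfg.fraction_positive * cfg.n_cells))
    n_neg = int(round(cfg.fraction_negative * cfg.n_cells))
    cats = np.array(["positive"] * n_pos + ["negative"] * n_neg
                    + ["none"] * (cfg.n_cells - n_pos - n_neg), dtype=object)
    rng.shuffle(cats)
    return cats


def generate_cell_session(cfg: SynthConfig,
                          taus: tuple[float, float] | None = None):
    """Cells x time dF/F matrix with heterogeneous CS responders.

    Positive cells add a CS-locked transient, negative cells subtract one,
    ``none`` cells are noise-only; amplitudes are
    ``effect_size * noise_sd * group_gain``. Returns
    ``(CellMatrix, EventSchedule, GroundTruth)``.
    """
    if cfg.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    length = cfg.resolved_length()
    ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(ss)
    cell_rngs = [np.random.default_rng(c) for c in ss.spawn(cfg.n_cells)]

    cats = _assign_categories(cfg, master)
    tr, td = taus if taus is not None else (cfg.tau_rise, cfg.tau_decay)
    kernel = _double_exp_kernel(cfg.sampling_rate, tr, td)
    amp = cfg.effect_size * cfg.noise_sd * cfg.group_gain
    onsets = cfg.cs_onsets()
    onset_idx = np.round(onsets * cfg.sampling_rate).astype(int)
    n = int(round(length * cfg.sampling_rate))

    sign = {"positive": 1.0, "negative": -1.0, "none": 0.0}
    data = np.empty((cfg.n_cells, n))
    amps = np.empty(cfg.n_cells)
    for ci in range(cfg.n_cells):
        trace = _noise(cell_rngs[ci], n, cfg.noise_sd, cfg.ar1)
        a = sign[cats[ci]] * amp
        for i in onset_idx:
            _add_kernel(trace, i, kernel, a)
        data[ci] = trace
        amps[ci] = a

    centroids = master.uniform(0, 100, size=(cfg.n_cells, 2)) if cfg.with_centroids else None
    sched = EventSchedule.from_events("CS_onset", onsets,
                                      np.full(onsets.size, cfg.cs_duration))
    cm = CellMatrix(data, cfg.sampling_rate, schedule=sched, centroids=centroids)
    truth = GroundTruth(category=cats, amplitude=amps,
                        group="A" if cfg.group_gain else "B")
    return cm, sched, truth


def generate_spike_session(cfg: SynthConfig):
    """Poisson spike trains with epoch-dependent rates and pip-locked boosts.

    Each of ``n_cells`` units fires as a piecewise-homogeneous Poisson
    process: ``baseline_rate`` everywhere, overridden by ``freeze_rate`` /
    ``move_rate`` inside the respective epochs, plus ``pip_boost`` Hz inside
    the first ``pip_boost_window`` after each pip onset. Returns
    ``(list[SpikeTrain], PipSchedule, EpochSet, GroundTruth)``.
    """
    length = cfg.resolved_length()
    ss = np.random.SeedSequence(cfg.seed)
    unit_rngs = [np.random.default_rng(c) for c in ss.spawn(cfg.n_cells)]

    pip_onsets = np.concatenate(
        [t + cfg.pip_period * np.arange(cfg.pips_per_cs) for t in cfg.cs_onsets()])
    pips = PipSchedule(pip_onsets, cfg.pip_duration)

    if cfg.epoch_block_s is not None:
        blocks = _movement_schedule(cfg, length)
        freeze = np.array([(t, t + d) for lab, t, d in blocks if lab == "freeze"]
                          ).reshape(-1, 2)
        move = np.array([(t, t + d) for lab, t, d in blocks if lab == "move"]
                        ).reshape(-1, 2)
    else:
        freeze = np.empty((0, 2))
        move = np.empty((0, 2))
    epochs = EpochSet(freeze, move)

    f_rate = cfg.baseline_rate if cfg.freeze_rate is None else cfg.freeze_rate
    m_rate = cfg.baseline_rate if cfg.move_rate is None else cfg.move_rate

    # breakpoints of the piecewise-constant rate function
    edges = {0.0, length}
    for iv in (freeze, move):
        for a, b in iv:
            edges.update((a, b))
    for t in pip_onsets:
        edges.update((t, min(t + cfg.pip_boost_window, length)))
    edges = np.array(sorted(e for e in edges if 0 <= e <= length))

    def _rate_at(t: float) -> float:
        r = cfg.baseline_rate
        if freeze.size and np.any((freeze[:, 0] <= t) & (t < freeze[:, 1])):
            r = f_rate
        elif move.size and np.any((move[:, 0] <= t) & (t < move[:, 1])):
            r = m_rate
        if cfg.pip_boost and np.any((pip_onsets <= t) & (t < pip_onsets + cfg.pip_boost_window)):
            r += cfg.pip_boost
        return r

    seg_rates = np.array([_rate_at((a + b) / 2) for a, b in zip(edges[:-1], edges[1:])])

    trains = []
    for ui in range(cfg.n_cells):
        rng = unit_rngs[ui]
        times = []
        for (a, b), r in zip(zip(edges[:-1], edges[1:]), seg_rates):
            if r <= 0 or b <= a:
                continue
            k = rng.poisson(r * (b - a))
            if k:
                times.append(rng.uniform(a, b, size=k))
        spikes = np.sort(np.concatenate(times)) if times else np.array([])
        trains.append(SpikeTrain(ui, spikes))

    truth = GroundTruth(rates={"baseline": cfg.baseline_rate, "freeze": f_rate,
                               "move": m_rate, "pip_boost": cfg.pip_boost})
    return trains, pips, epochs, truth


# --------------------------------------------------------------------------- #
# serialisation: NPY arrays with a JSON sidecar, schedules as CSV
# --------------------------------------------------------------------------- #

def save_cell_session(outdir: str | Path, cm: CellMatrix, sched: EventSchedule,
                      truth: GroundTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "dff.npy", cm.data)
    sidecar = {"sampling_rate": cm.sampling_rate, "t0": 0.0,
               "cell_ids": [int(i) for i in cm.cell_ids], "stage": cm.stage}
    (outdir / "dff.json").write_text(json.dumps(sidecar, indent=1))
    if cm.centroids is not None:
        np.save(outdir / "centroids.npy", cm.centroids)
    sched.to_csv(outdir / "schedule.csv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")


def load_cell_session(outdir: str | Path) -> tuple[CellMatrix, EventSchedule]:
    outdir = Path(outdir)
    data = np.load(outdir / "dff.npy")
    meta = json.loads((outdir / "dff.json").read_text())
    sched = EventSchedule.from_csv(outdir / "schedule.csv")
    centroids_path = outdir / "centroids.npy"
    centroids = np.load(centroids_path) if centroids_path.exists() else None
    return (CellMatrix(data, meta["sampling_rate"], schedule=sched,
                       cell_ids=np.asarray(meta["cell_ids"]),
                       centroids=centroids, stage=meta.get("stage", "")), sched)
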