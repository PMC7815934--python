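"""Integrate-and-fire network simulator and Spearman-window microcircuit builder.

The simulated network has two neuron groups.  Group A (default 50 neurons)
has no parents and is driven by a Poisson stimulus; group B (default 50)
receives synaptic input from a fixed random set of group-A parents.  Two
experimental conditions differ only in wiring density: in condition 1 each B
neuron has 1-2 parents, in condition 2 it has 3-4.  Denser parentage makes B
activity more coherent with group A, which is the signal a weighted
graph-level embedding should pick up.

Each neuron follows a leaky integrate-and-fire model with additive noise,

    d rho / dt = (rho_rest - rho) / tau + sigma * tau^(-1/2) * eps,

with eps ~ N(0, 1), Euler-integrated at step ``dt``.  Stimulus and synaptic
events add fixed increments to rho; crossing ``spike_threshold`` emits a
spike, resets rho to rest and silences the neuron for the refractory period.

Microcircuits are built from the membrane-potential traces: the activity is
cut into non-overlapping windows and, within each window, every neuron pair
receives an edge weighted by the Spearman rank correlation of the two
potential series.  One complete weighted graph per window; no thresholding
happens here (the multi-channel embedding owns all thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_graphs import Microcircuit, MicrocircuitDataset, UnweightedGraph


@dataclass(frozen=True)
class NeuronParams:
    """Neuron model constants (arbitrary units; time in integration steps).

    Defaults: rest at 0, unit spike threshold, membrane time constant 20
    steps, noise scale 0.1, 2-step refractory period, unit Euler step.
    """

    rho_rest: float = 0.0
    tau: float = 20.0
    sigma: float = 0.1
    spike_threshold: float = 1.0
    refractory: int = 2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.rho_rest, self.tau, self.sigma, self.spike_threshold, self.dt]).all():
            raise ValueError("neuron parameters must be finite")
        if self.tau <= 0 or self.dt <= 0 or self.refractory < 0:
            raise ValueError("require tau > 0, dt > 0, refractory >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Network and protocol parameters for one simulated condition.

    ``condition`` selects the parents-per-B-neuron range: {1,2} for
    condition 1 and {3,4} for condition 2.  ``stimulus_rate`` is the
    per-step Poisson probability of a stimulus event on each group-A neuron;
    ``stimulus_amplitude`` (suprathreshold by default) and
    ``synaptic_increment`` are added to rho on stimulus/parent-spike events.
    ``window`` is the number of frames per Spearman correlation window.
    """

    n_a: int = 50
    n_b: int = 50
    condition: int = 1
    stimulus_rate: float = 0.05
    stimulus_amplitude: float = 1.2
    synaptic_increment: float = 0.4
    duration: int = 400
    window: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in (1, 2):
            raise ValueError(f"condition must be 1 or 2, got {self.condition}")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("n_a and n_b must be >= 1")
        if self.duration < 1 or self.window < 3:
            raise ValueError("require duration >= 1 and window >= 3")

    @property
    def n_neurons(self) -> int:
        return self.n_a + self.n_b

    @property
    def parent_range(self) -> tuple[int, int]:
        return (1, 2) if self.condition == 1 else (3, 4)


@dataclass(frozen=True)
class ActivityTrace:
    """Per-neuron simulated activity: potentials and spike indicators.

    Both arrays have shape (n_neurons, n_frames); row order is group A then
    group B.
    """

    potentials: np.ndarray
    spikes: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_frames(self) -> int:
        return self.potentials.shape[1]


def simulate_condition(
    cfg: SimulationConfig, params: NeuronParams | None = None
) -> ActivityTrace:
    """Euler-integrate the network for ``cfg.duration`` steps.

    Group-B parent wiring is drawn once per call from the condition's parent
    range.  Synaptic events propagate with one step of delay (a spike at
    frame t increments children at frame t+1).  Deterministic given
    ``cfg.seed``.
    """
    params = params or NeuronParams()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons

    # Parent adjacency: (n_b, n_a) 0/1 matrix, row sums in the parent range.
    lo, hi = cfg.parent_range
    parents = np.zeros((cfg.n_b, cfg.n_a))
    for b in range(cfg.n_b):
        n_par = rng.integers(lo, hi + 1)
        parents[b, rng.choice(cfg.n_a, size=n_par, replace=False)] = 1.0

    dt, tau = params.dt, params.tau
    noise_scale = params.sigma * np.sqrt(dt / tau)

    rho = np.full(n, params.rho_rest)
    refr = np.zeros(n, dtype=int)
    prev_a_spikes = np.zeros(cfg.n_a)

    potentials = np.empty((n, cfg.duration))
    spikes = np.zeros((n, cfg.duration), dtype=bool)

    for t in range(cfg.duration):
        drive = np.zeros(n)
        stim = rng.random(cfg.n_a) < cfg.stimulus_rate * dt
        drive[: cfg.n_a][stim] += cfg.stimulus_amplitude
        drive[cfg.n_a :] += cfg.synaptic_increment * (parents @ prev_a_spikes)

        eps = rng.standard_normal(n)
        active = refr == 0
        leak = dt * (params.rho_rest - rho) / tau
        rho = np.where(active, rho + leak + noise_scale * eps + drive, rho)

        fired = active & (rho > params.spike_threshold)
        potentials[:, t] = rho
        spikes[:, t] = fired

        rho[fired] = params.rho_rest
        refr[refr > 0] -= 1
        refr[fired] = params.refractory
        prev_a_spikes = fired[: cfg.n_a].astype(float)

    return ActivityTrace(potentials=potentials, spikes=spikes)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN for a constant input series (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _window_correlations(segment: np.ndarray) -> np.ndarray:
    """All-pairs Spearman matrix for one (n_neurons, window) segment."""
    ranks = stats.rankdata(segment, axis=1)
    sd = ranks.std(axis=1)
    # Pearson on ranks == Spearman (average-rank tie handling).
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr[~np.isfinite(corr)] = 0.0  # constant series: undefined -> 0
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    return corr


def build_microcircuits(trace: ActivityTrace, window: int) -> MicrocircuitDataset:
    """One complete weighted graph per non-overlapping window of the trace.

    Edge weight for each neuron pair is the Spearman correlation of the two
    potential series within the window.  Undefined correlations (constant
    series) are recorded as weight 0.
    """
    if window < 3:
        raise ValueError("window must be >= 3 frames")
    if trace.n_frames < window:
        raise ValueError(
            f"trace has {trace.n_frames} frames, shorter than window {window}"
        )
    n = trace.n_neurons
    pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
    members = []
    n_windows = trace.n_frames // window
    structure = UnweightedGraph.from_edges(n, pairs)
    for w in range(n_windows):
        seg = trace.potentials[:, w * window : (w + 1) * window]
        corr = _window_correlations(seg)
        weights = {(i, j): float(corr[i - 1, j - 1]) for i, j in pairs}
        members.append(Microcircuit(structure, weights))
    return MicrocircuitDataset(members=members, common_vertex_count=n)


def generate_simu_dataset(
    n0: int,
    n1: int,
    cfg: SimulationConfig | None = None,
    params: NeuronParams | None = None,
    seed: int = 0,
) -> MicrocircuitDataset:
    """Labeled two-condition dataset: n0 graphs of condition 1, n1 of condition 2.

    Each condition is simulated long enough to cut the requested number of
    windows; labels are 0 for condition 1 and 1 for condition 2.
    """
    if n0 < 1 or n1 < 1:
        raise ValueError("n0 and n1 must be >= 1")
    cfg = cfg or SimulationConfig()
    members: list = []
    labels: list[int] = []
    for condition, count, label in ((1, n0, 0), (2, n1, 1)):
        sub = replace(
            cfg,
            condition=condition,
            duration=count * cfg.window,
            seed=seed + condition,
        )
        trace = simulate_condition(sub, params)
        d = build_microcircuits(trace, cfg.window)
        members.extend(d.members)
        labels.extend([label] * len(d))
    return MicrocircuitDataset(
        members=members,
        common_vertex_count=cfg.n_neurons,
        labels=labels,
    )
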