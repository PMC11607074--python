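"""Synthetic smFRET trace generation for the recombinase rotation cycle.

The strand-exchange cycle is modelled as a continuous-time Markov chain on the
linear four-state chain ``lnr ⇌ cnr ⇌ cr ⇌ lr`` (ligated/cleaved,
non-recombinant/recombinant).  State paths are drawn by exact stochastic
(Gillespie) simulation and rendered as camera traces: per-frame donor and
acceptor counts at a fixed exposure, with time-weighted averaging of mid-frame
transitions (the origin of frame-blurring and "skipped state" artefacts),
additive Gaussian or Poisson intensity noise, and independent single-step
donor/acceptor photobleaching clocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trace_io import IntensityTrace

#: FRET efficiency level per state, per experimental condition.  Values are
#: the apparent-E state means reported for each system; rotation rates are the
#: cnr→cr / cr→cnr rate constants for the same condition.  Cleavage/ligation
#: rates are not condition-resolved in the sources available and default to a
#: documented placeholder of 1.0 /s (see docs/methods.md).
PRESET_STATE_MEANS: dict[str, tuple[float, float, float, float]] = {
    "sin37": (0.16, 0.29, 0.50, 0.77),
    "sin37_mg": (0.13, 0.29, 0.53, 0.79),
    "sin21": (0.17, 0.34, 0.54, 0.78),
    "tn3": (0.12, 0.31, 0.54, 0.73),
}

PRESET_ROTATION_RATES: dict[str, tuple[float, float]] = {
    "sin37": (0.86, 0.48),
    # rotation rates for Mg2+/21 °C conditions are not printed; the 37 °C
    # values are placeholders for these presets
    "sin37_mg": (0.86, 0.48),
    "sin21": (0.86, 0.48),
    "tn3": (1.14, 0.41),
}

STATE_NAMES = ("lnr", "cnr", "cr", "lr")


class SimulationError(ValueError):
    """Invalid simulation input."""


@dataclass(frozen=True)
class KineticScheme:
    """Rate model for the linear four-state recombination chain.

    Only nearest-neighbour transitions carry nonzero rates:

    ``lnr --k_cle--> cnr --k_rec--> cr --k_lig_r--> lr``
    ``lnr <--k_lig_nr-- cnr <--k_non_rec-- cr <--k_cle_r-- lr``

    k_rec and k_non_rec are the forward/reverse 180° subunit-rotation rates;
    k_cle/k_lig are cleavage and ligation rates on either side of the cycle.
    All rates in 1/s.
    """

    k_cle: float = 1.0
    k_lig_nr: float = 1.0
    k_rec: float = 0.86
    k_non_rec: float = 0.48
    k_lig_r: float = 1.0
    k_cle_r: float = 1.0
    state_names: tuple[str, ...] = STATE_NAMES

    def __post_init__(self) -> None:
        for name in ("k_cle", "k_lig_nr", "k_rec", "k_non_rec", "k_lig_r", "k_cle_r"):
            if getattr(self, name) < 0:
                raise SimulationError(f"rate {name} must be >= 0")

    def rate_matrix(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = np.zeros((4, 4))
        q[0, 1] = self.k_cle
        q[1, 0] = self.k_lig_nr
        q[1, 2] = self.k_rec
        q[2, 1] = self.k_non_rec
        q[2, 3] = self.k_lig_r
        q[3, 2] = self.k_cle_r
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        return stationary_distribution(self.rate_matrix())

    @classmethod
    def preset(cls, name: str) -> "KineticScheme":
        if name not in PRESET_ROTATION_RATES:
            raise SimulationError(
                f"unknown preset {name!r}; choose from {sorted(PRESET_ROTATION_RATES)}"
            )
        k_rec, k_non_rec = PRESET_ROTATION_RATES[name]
        return cls(k_rec=k_rec, k_non_rec=k_non_rec)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator via the null space of Qᵀ."""
    q = np.asarray(q, dtype=float)
    _, _, vh = np.linalg.svd(q.T)
    pi = np.abs(vh[-1])
    return pi / pi.sum()


@dataclass(frozen=True)
class EmissionModel:
    """Photophysical model mapping a state path to camera counts.

    state_means: apparent FRET efficiency per state (E units, in [0, 1]).
    total_intensity: mean summed donor+acceptor counts per frame.
    noise_sd: additive per-channel Gaussian noise SD (counts); ignored when
        ``noise="poisson"``.
    donor_bleach_rate / acceptor_bleach_rate: exponential single-step
        photobleaching rates (1/s); 0 disables the clock.
    exposure: camera frame integration time (s).
    gamma, beta: detection-efficiency ratio and donor→acceptor crosstalk used
        when splitting intensity between the channels.
    """

    state_means: tuple[float, ...] = PRESET_STATE_MEANS["sin37"]
    total_intensity: float = 1000.0
    noise_sd: float = 30.0
    noise: str = "gaussian"
    donor_bleach_rate: float = 0.005
    acceptor_bleach_rate: float = 0.01
    exposure: float = 0.05
    gamma: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise SimulationError("exposure must be > 0")
        if any(not (0.0 <= m <= 1.0) for m in self.state_means):
            raise SimulationError("state means must lie in [0, 1]")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise SimulationError("bleach rates must be >= 0")
        if self.noise not in ("gaussian", "poisson"):
            raise SimulationError("noise must be 'gaussian' or 'poisson'")

    @classmethod
    def preset(cls, name: str, **overrides) -> "EmissionModel":
        if name not in PRESET_STATE_MEANS:
            raise SimulationError(
                f"unknown preset {name!r}; choose from {sorted(PRESET_STATE_MEANS)}"
            )
        return cls(state_means=PRESET_STATE_MEANS[name], **overrides)


@dataclass(frozen=True)
class ContinuousPath:
    """Exact (continuous-time) state path: contiguous labelled segments."""

    segments: tuple[tuple[str, float, float], ...]
    duration: float

    def __post_init__(self) -> None:
        t = 0.0
        prev_state = None
        for state, t0, t1 in self.segments:
            if not np.isclose(t0, t) or t1 < t0:
                raise SimulationError("segments must be contiguous and ordered")
            if state == prev_state:
                raise SimulationError("consecutive segments must differ in state")
            prev_state, t = state, t1
        if self.segments and not np.isclose(t, self.duration):
            raise SimulationError("segments must cover [0, duration]")

    def state_at(self, t: float) -> str:
        for state, t0, t1 in self.segments:
            if t0 <= t < t1:
                return state
        return self.segments[-1][0]

    def occupancy(self) -> dict[str, float]:
        """Fraction of total time spent in each visited state."""
        occ: dict[str, float] = {}
        for state, t0, t1 in self.segments:
            occ[state] = occ.get(state, 0.0) + (t1 - t0)
        return {s: v / self.duration for s, v in occ.items()}

    def dwell_times(self, interior_only: bool = True) -> dict[str, np.ndarray]:
        """Dwell times per state; first/last segments are right/left censored."""
        segs = self.segments[1:-1] if interior_only else self.segments
        out: dict[str, list[float]] = {}
        for state, t0, t1 in segs:
            out.setdefault(state, []).append(t1 - t0)
        return {s: np.asarray(v) for s, v in out.items()}


def simulate_ctmc(
    q: np.ndarray,
    state_names: tuple[str, ...],
    duration: float,
    initial_state: str,
    seed: int | np.random.Generator | None = None,
) -> ContinuousPath:
    """Exact stochastic (Gillespie) realization of a CTMC over ``duration`` s.

    Waiting times are exponential with rate equal to the total exit rate of
    the current state; the successor is drawn proportionally to the individual
    transition rates.  A state with zero exit rate absorbs for the remaining
    time.
    """
    if duration <= 0:
        raise SimulationError("duration must be > 0")
    if initial_state not in state_names:
        raise SimulationError(f"unknown initial state {initial_state!r}")
    rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    idx = {s: i for i, s in enumerate(state_names)}

    segments: list[tuple[str, float, float]] = []
    state = idx[initial_state]
    t = 0.0
    while t < duration:
        rates = q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0.0:
            segments.append((state_names[state], t, duration))
            break
        dt = rng.exponential(1.0 / total)
        t_exit = min(t + dt, duration)
        segments.append((state_names[state], t, t_exit))
        if t + dt >= duration:
            break
        state = rng.choice(len(state_names), p=rates / total)
        t = t_exit
    return ContinuousPath(segments=tuple(segments), duration=duration)


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    initial_state: str = "lnr",
    seed: int | np.random.Generator | None = None,
) -> ContinuousPath:
    """Gillespie realization of the four-state recombination scheme."""
    return simulate_ctmc(scheme.rate_matrix(), scheme.state_names, duration, initial_state, seed)


def _frame_mean_e(
    path: ContinuousPath, means: dict[str, float], edges: np.ndarray
) -> np.ndarray:
    """Time-weighted mean FRET per frame from the exact segment overlaps."""
    n = len(edges) - 1
    acc = np.zeros(n)
    for state, t0, t1 in path.segments:
        i0 = max(0, int(np.searchsorted(edges, t0, side="right")) - 1)
        i1 = min(n - 1, int(np.searchsorted(edges, t1, side="left")) - 1)
        for i in range(i0, i1 + 1):
            overlap = min(t1, edges[i + 1]) - max(t0, edges[i])
            if overlap > 0:
                acc[i] += overlap * means[state]
    return acc / (edges[1] - edges[0])


def render_trace(
    path: ContinuousPath,
    emission: EmissionModel,
    seed: int | np.random.Generator | None = None,
    trace_id: str = "trace",
    state_means: dict[str, float] | None = None,
) -> IntensityTrace:
    """Render a continuous state path as a camera-sampled intensity trace.

    Each frame integrates the FRET signal over its exposure window
    (time-weighted over the overlapping path segments), then splits the total
    intensity into the donor/acceptor channels, applies the photobleaching
    clocks and adds channel noise.  After acceptor bleach all emission appears
    in the donor channel (E drops to zero); after donor bleach both channels
    fall to background.

    Returns the trace; the drawn bleach times are attached as
    ``trace.meta["donor_bleach_time"]`` / ``["acceptor_bleach_time"]``.
    """
    rng = np.random.default_rng(seed)
    dt = emission.exposure
    n_frames = int(np.floor(path.duration / dt + 1e-9))
    if n_frames < 1:
        raise SimulationError("path shorter than one frame")
    edges = np.arange(n_frames + 1) * dt

    if state_means is None:
        visited = sorted({s for s, _, _ in path.segments})
        if len(visited) > len(emission.state_means):
            raise SimulationError("more states visited than state_means provided")
        if set(visited) <= set(STATE_NAMES) and len(emission.state_means) == 4:
            state_means = dict(zip(STATE_NAMES, emission.state_means))
        else:
            state_means = dict(zip(visited, emission.state_means))
    mean_e = _frame_mean_e(path, state_means, edges)

    t_donor = (
        rng.exponential(1.0 / emission.donor_bleach_rate)
        if emission.donor_bleach_rate > 0
        else np.inf
    )
    t_acceptor = (
        rng.exponential(1.0 / emission.acceptor_bleach_rate)
        if emission.acceptor_bleach_rate > 0
        else np.inf
    )

    # per-frame fraction of exposure with both dyes active, and with the
    # acceptor dark but the donor still emitting
    t_dark = t_donor
    t_donor_only_start = min(t_acceptor, t_dark)
    f_active = np.clip(t_donor_only_start - edges[:-1], 0.0, dt) / dt
    f_alive = np.clip(t_dark - edges[:-1], 0.0, dt) / dt
    f_donor_only = np.clip(f_alive - f_active, 0.0, 1.0)

    itot = emission.total_intensity
    e_eff = f_active * mean_e
    donor = itot * (f_active * (1.0 - mean_e) + f_donor_only)
    acceptor = emission.gamma * itot * e_eff + emission.beta * donor

    if emission.noise == "poisson":
        donor = rng.poisson(np.clip(donor, 0.0, None)).astype(float)
        acceptor = rng.poisson(np.clip(acceptor, 0.0, None)).astype(float)
    elif emission.noise_sd > 0:
        donor = donor + rng.normal(0.0, emission.noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, emission.noise_sd, n_frames)

    trace = IntensityTrace(
        trace_id=trace_id, donor=donor, acceptor=acceptor, exposure=dt
    )
    trace.meta["donor_bleach_time"] = float(t_donor)
    trace.meta["acceptor_bleach_time"] = float(t_acceptor)
    return trace


@dataclass
class SyntheticDataset:
    """Rendered traces plus the ground truth that generated them."""

    traces: list[IntensityTrace]
    paths: list[ContinuousPath]
    donor_only: np.ndarray  # bool per trace
    scheme: KineticScheme
    emission: EmissionModel
    seed: int | None = None

    def ground_truth_table(self):
        """Sidecar table (trace_id, state, t_entry, t_exit) of the true paths."""
        import pandas as pd

        rows = []
        for trace, path in zip(self.traces, self.paths):
            for state, t0, t1 in path.segments:
                rows.append((trace.trace_id, state, t0, t1))
        return pd.DataFrame(rows, columns=["trace_id", "state", "t_entry", "t_exit"])


def generate_dataset(
    scheme: KineticScheme,
    emission: EmissionModel,
    n_traces: int,
    duration: float = 25.0,
    seed: int | None = None,
    donor_only_fraction: float = 0.0,
    initial_state: str | None = None,
) -> SyntheticDataset:
    """Generate independent traces with per-trace derived seeds.

    Initial states are drawn from the stationary distribution of the scheme
    unless ``initial_state`` is given.  A ``donor_only_fraction`` of traces is
    replaced by the zero-FRET (acceptor-absent) nuisance population seen in
    real TIRF fields.
    """
    if n_traces < 1:
        raise SimulationError("n_traces must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces + 1)
    master = np.random.default_rng(children[0])
    pi = scheme.stationary_distribution()
    donor_only = master.random(n_traces) < donor_only_fraction
    zero_fret = replace(emission, state_means=(0.0,) * len(emission.state_means))

    traces, paths = [], []
    for i in range(n_traces):
        rng = np.random.default_rng(children[i + 1])
        init = (
            initial_state
            if initial_state is not None
            else scheme.state_names[rng.choice(len(pi), p=pi)]
        )
        path = simulate_state_path(scheme, duration, init, rng)
        em = zero_fret if donor_only[i] else emission
        traces.append(render_trace(path, em, rng, trace_id=f"trace{i:04d}"))
        paths.append(path)
    return SyntheticDataset(
        traces=traces,
        paths=paths,
        donor_only=donor_only,
        scheme=scheme,
        emission=emission,
        seed=seed,
    )
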