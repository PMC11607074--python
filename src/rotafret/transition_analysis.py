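"""Transition density plots and constrained mixture clustering.

Every state change in the idealized paths yields a transition record
(E before, E after, dwell in the preceding state).  Pooled over all traces,
the records form the transition density plot (TDP).  The number of FRET
states K is inferred by maximum-likelihood fitting of a *constrained* mixture
of K(K−1) isotropic 2D Gaussians — the cluster centres are the Cartesian
pairs (E_i, E_j), i ≠ j, of K shared state levels — followed by BIC model
selection over a K range with many random initializations.  The mixture is
fitted on the raw transition points; the Gaussian-convolved grid is for
display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import logsumexp

from .hmm_segmentation import IdealizedPath

CLUSTER_VARIANCE_FLOOR = 1e-4  # in E^2


class ClusteringError(ValueError):
    """Not enough transitions (or all fits failed)."""


@dataclass(frozen=True)
class TransitionRecord:
    """One observed state change with the dwell in the departed state.

    ``truncated_left`` marks records whose preceding run starts the trace
    (left-censored dwell, excluded from kinetics); ``truncated_right`` marks
    the last transition of a trace.
    """

    trace_id: str
    e_before: float
    e_after: float
    dwell_before: float
    truncated_left: bool = False
    truncated_right: bool = False


def extract_transitions(
    paths: list[IdealizedPath],
    min_delta_e: float = 0.0,
    level_source: str = "fitted",
) -> list[TransitionRecord]:
    """One record per state change; dwell = preceding constant-run length × exposure.

    ``level_source`` picks the E coordinate of each record: ``"fitted"`` uses
    the trace's fitted state level (the model mean), ``"dwell_mean"`` the
    observed mean E over the dwell itself — the classic TDP coordinate, which
    is robust to per-trace fits that merged two briefly-visited states into
    one intermediate level.

    ``min_delta_e`` drops records with |E_after − E_before| below the
    threshold: fixed-K idealization of traces that visit fewer states places
    near-duplicate levels on one population, and flicker between those
    duplicates is decoding noise, not a conformational transition.  Runs are
    merged across dropped boundaries so dwell times stay contiguous.
    """
    if level_source not in ("fitted", "dwell_mean"):
        raise ValueError("level_source must be 'fitted' or 'dwell_mean'")
    records: list[TransitionRecord] = []
    for path in paths:
        states = path.states
        if states.size < 2:
            continue
        change = np.flatnonzero(np.diff(states) != 0)
        if change.size == 0:
            continue
        run_starts = np.concatenate(([0], change + 1))
        run_ends = np.concatenate((change + 1, [states.size]))
        if level_source == "dwell_mean" and path.e_raw is not None:
            run_levels = np.array(
                [float(np.mean(path.e_raw[a:b])) for a, b in zip(run_starts, run_ends)]
            )
        else:
            run_levels = path.levels[run_starts]
        run_lengths = np.diff(np.concatenate((run_starts, [states.size])))
        if min_delta_e > 0:
            merged: list[list[float]] = [[run_levels[0], run_lengths[0]]]
            for lev, length in zip(run_levels[1:], run_lengths[1:]):
                cur = merged[-1]
                if abs(lev - cur[0]) < min_delta_e:
                    total = cur[1] + length
                    cur[0] = (cur[0] * cur[1] + lev * length) / total
                    cur[1] = total
                else:
                    merged.append([lev, length])
            run_levels = np.array([m[0] for m in merged])
            run_lengths = np.array([m[1] for m in merged])
        for r in range(run_levels.size - 1):
            records.append(
                TransitionRecord(
                    trace_id=path.trace_id,
                    e_before=float(run_levels[r]),
                    e_after=float(run_levels[r + 1]),
                    dwell_before=float(run_lengths[r]) * path.exposure,
                    truncated_left=(r == 0),
                    truncated_right=(r + 1 == run_levels.size - 1),
                )
            )
    return records


def records_to_points(records: list[TransitionRecord]) -> np.ndarray:
    return np.array([(r.e_before, r.e_after) for r in records], dtype=float).reshape(-1, 2)


@dataclass
class TdpGrid:
    """Gaussian-convolved 2D histogram of (E before, E after) over [0, 1]²."""

    edges: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def n_bins(self) -> int:
        return self.density.shape[0]


def build_tdp(
    records: list[TransitionRecord], n_bins: int = 100, bandwidth: float = 0.02
) -> TdpGrid:
    """Histogram the transition points and convolve with an isotropic kernel.

    ``bandwidth`` is the kernel SD in E units; 0 returns the raw histogram.
    The convolution conserves counts away from the plot border.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pts = records_to_points(records)
    if pts.size == 0:
        warnings.warn("no transition records; TDP grid is empty", stacklevel=2)
        return TdpGrid(edges=edges, density=np.zeros((n_bins, n_bins)), bandwidth=bandwidth)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
    if bandwidth > 0:
        hist = gaussian_filter(hist, sigma=bandwidth * n_bins, mode="constant")
    return TdpGrid(edges=edges, density=hist, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# constrained K(K-1) mixture


def cluster_pairs(k: int) -> list[tuple[int, int]]:
    """Ordered state pairs (i, j), i ≠ j, indexing the K(K−1) clusters."""
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass
class TdpClusterModel:
    """Fitted constrained mixture for one K (possibly the BIC winner).

    ``levels`` are the K shared state levels (sorted ascending); cluster c
    with pair (i, j) is centred at (levels[i], levels[j]) with isotropic SD
    ``sds[c]`` and weight ``weights[c]`` (weights sum to 1 over all ordered
    pairs).
    """

    k: int
    levels: np.ndarray
    weights: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_records: int
    bic_by_k: dict[int, float] = field(default_factory=dict)
    is_k_opt: bool = False
    background: tuple[float, float, float] | None = None  # K=1: (cx, cy, sd)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return cluster_pairs(self.k)

    @property
    def n_params(self) -> int:
        if self.k == 1:
            return 3  # free 2D centre + isotropic variance of the null background
        c = self.k * (self.k - 1)
        return self.k + (c - 1) + c

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_records)

    def level_sds(self) -> np.ndarray:
        """Per-level SD: average cluster SD over clusters touching each level,
        weighted by cluster weight (the 'average Gaussian sample SD')."""
        out = np.zeros(self.k)
        for lev in range(self.k):
            num = den = 0.0
            for c, (i, j) in enumerate(self.pairs):
                if lev in (i, j):
                    num += self.weights[c] * self.sds[c]
                    den += self.weights[c]
            out[lev] = num / den if den > 0 else 0.0
        return out

    def log_responsibilities(self, points: np.ndarray) -> np.ndarray:
        logp = _cluster_logpdf(points, self.levels, self.sds, self.pairs)
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(self.weights, 1e-300))
        joint = logp + logw[None, :]
        return joint - logsumexp(joint, axis=1, keepdims=True)

    def assign(self, records: list[TransitionRecord]) -> np.ndarray:
        """Maximum-responsibility cluster index per record (deterministic)."""
        pts = records_to_points(records)
        return np.argmax(self.log_responsibilities(pts), axis=1)


def _cluster_logpdf(
    points: np.ndarray, levels: np.ndarray, sds: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """(N, C) isotropic 2D Gaussian log densities at the pair centres."""
    a = (points[:, 0][:, None] - levels[None, :]) ** 2
    b = (points[:, 1][:, None] - levels[None, :]) ** 2
    pi_idx = np.array([p[0] for p in pairs])
    pj_idx = np.array([p[1] for p in pairs])
    d2 = a[:, pi_idx] + b[:, pj_idx]
    var = sds[None, :] ** 2
    return -np.log(2 * np.pi * var) - d2 / (2 * var)


def _fit_k1(points: np.ndarray) -> tuple[float, tuple[float, float, float]]:
    """Null model: one broad isotropic background component."""
    centre = points.mean(axis=0)
    var = max(float(np.mean(np.sum((points - centre) ** 2, axis=1)) / 2.0), CLUSTER_VARIANCE_FLOOR)
    n = points.shape[0]
    logl = float(-n * np.log(2 * np.pi * var) - n)  # = sum of logpdf at the MLE
    return logl, (float(centre[0]), float(centre[1]), float(np.sqrt(var)))


def _init_params(
    points: np.ndarray, k: int, rng: np.random.Generator, jitter: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pooled = np.concatenate([points[:, 0], points[:, 1]])
    levels = np.quantile(pooled, (np.arange(k) + 0.5) / k)
    if jitter > 0:
        levels = levels + rng.normal(0.0, jitter, k)
    c = k * (k - 1)
    return levels, np.full(c, 1.0 / c), np.full(c, 4e-4)


def _em_constrained(
    points: np.ndarray,
    k: int,
    params: tuple[np.ndarray, np.ndarray, np.ndarray],
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """EM from given (levels, weights, variances); returns them converged.

    The M-step for the shared levels is precision-weighted over every cluster
    whose centre uses the level on either axis.
    """
    n = points.shape[0]
    pairs = cluster_pairs(k)
    pi_idx = np.array([p[0] for p in pairs])
    pj_idx = np.array([p[1] for p in pairs])
    x0, x1 = points[:, 0], points[:, 1]
    levels, weights, variances = (np.array(p, dtype=float) for p in params)

    logl_prev = -np.inf
    for _ in range(max_iter):
        a = (x0[:, None] - levels[None, :]) ** 2
        b = (x1[:, None] - levels[None, :]) ** 2
        d2 = a[:, pi_idx] + b[:, pj_idx]
        joint = (
            np.log(np.maximum(weights, 1e-300)) - np.log(2 * np.pi * variances)
        )[None, :] - d2 / (2 * variances[None, :])
        mx = joint.max(axis=1)
        ex = np.exp(joint - mx[:, None])
        se = ex.sum(axis=1)
        logl = float(np.sum(mx + np.log(se)))
        resp = ex / se[:, None]

        nc = resp.sum(axis=0)
        weights = nc / n
        sq = (resp * d2).sum(axis=0)
        variances = np.maximum(sq / (2 * np.maximum(nc, 1e-12)), CLUSTER_VARIANCE_FLOOR)

        s0 = resp.T @ x0
        s1 = resp.T @ x1
        inv_var = 1.0 / variances
        num = np.zeros(k)
        den = np.zeros(k)
        np.add.at(num, pi_idx, s0 * inv_var)
        np.add.at(num, pj_idx, s1 * inv_var)
        np.add.at(den, pi_idx, nc * inv_var)
        np.add.at(den, pj_idx, nc * inv_var)
        levels = np.where(den > 0, num / np.maximum(den, 1e-300), levels)

        if logl - logl_prev < tol * max(1.0, abs(logl)) and logl >= logl_prev:
            logl_prev = logl
            break
        logl_prev = logl
    return logl_prev, levels, weights, np.sqrt(variances)


def fit_tdp_mixture(
    records: list[TransitionRecord],
    k: int,
    n_init: int = 30,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    burn_in: int = 30,
) -> TdpClusterModel:
    """Best-of-``n_init`` EM fit of the constrained mixture for a single K.

    Every initialization is run for a short ``burn_in``; only the best is
    continued to convergence (standard multi-start economy — the ranking of
    starts stabilizes within a few tens of iterations).
    """
    points = records_to_points(records)
    n = points.shape[0]
    if n < 10:
        raise ClusteringError(f"need >= 10 transition records, got {n}")
    rng = np.random.default_rng(seed)

    if k == 1:
        logl, background = _fit_k1(points)
        return TdpClusterModel(
            k=1,
            levels=np.array([background[0]]),
            weights=np.ones(1),
            sds=np.array([background[2]]),
            log_likelihood=logl,
            n_records=n,
            background=background,
        )

    best = None
    for init in range(n_init):
        jitter = 0.0 if init == 0 else 0.05
        params = _init_params(points, k, rng, jitter)
        out = _em_constrained(points, k, params, burn_in, tol)
        if best is None or out[0] > best[0]:
            best = out
    _, levels, weights, sds = best
    logl, levels, weights, sds = _em_constrained(
        points, k, (levels, weights, sds**2), max_iter, tol
    )

    # canonicalize: sort levels ascending, remap cluster order accordingly
    order = np.argsort(levels)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    pairs = cluster_pairs(k)
    remapped = {(rank[i], rank[j]): c for c, (i, j) in enumerate(pairs)}
    perm = np.array([remapped[p] for p in pairs])
    return TdpClusterModel(
        k=k,
        levels=levels[order],
        weights=weights[perm] / weights.sum(),
        sds=sds[perm],
        log_likelihood=logl,
        n_records=n,
    )


def cluster_tdp(
    records: list[TransitionRecord],
    k_range: tuple[int, int] = (1, 10),
    n_init: int = 30,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> TdpClusterModel:
    """ML-BIC selection of the number of FRET states from the TDP.

    Fits the constrained K(K−1)-component mixture for each K in ``k_range``
    (``n_init`` seeded restarts each) and returns the BIC-minimal model;
    equal-BIC ties go to the smallest K.  K with more parameters than records
    are skipped with a diagnostic.
    """
    lo, hi = k_range
    rng = np.random.default_rng(seed)
    bics: dict[int, float] = {}
    models: dict[int, TdpClusterModel] = {}
    skipped: dict[int, str] = {}
    n = len(records)
    for k in range(lo, hi + 1):
        p = 3 if k == 1 else k + (k * (k - 1) - 1) + k * (k - 1)
        if n <= p:
            skipped[k] = f"{n} records <= {p} parameters"
            continue
        m = fit_tdp_mixture(records, k, n_init=n_init, seed=rng, max_iter=max_iter, tol=tol)
        models[k] = m
        bics[k] = m.bic
    if not models:
        raise ClusteringError(f"no K could be fitted: {skipped}")
    best_k = min(sorted(bics), key=lambda k: bics[k])
    best = models[best_k]
    best.bic_by_k = bics
    best.is_k_opt = True
    return best


def transition_counts(
    model: TdpClusterModel, records: list[TransitionRecord]
) -> dict[tuple[int, int], float]:
    """Relative number of transitions per ordered state pair (fractions sum to 1)."""
    if model.k == 1:
        return {}
    assignment = model.assign(records)
    counts = np.bincount(assignment, minlength=len(model.pairs)).astype(float)
    fractions = counts / counts.sum() if counts.sum() > 0 else counts
    return {pair: float(f) for pair, f in zip(model.pairs, fractions)}


def branching_weights(model: TdpClusterModel) -> dict[tuple[int, int], float]:
    """Per-from-state branching fraction of each cluster weight.

    w(i→j) / Σ_j' w(i→j'): the fraction of departures from state i that go to
    j, used to split a state's total exit rate over its transitions.
    """
    out: dict[tuple[int, int], float] = {}
    totals = np.zeros(model.k)
    for c, (i, _) in enumerate(model.pairs):
        totals[i] += model.weights[c]
    for c, (i, j) in enumerate(model.pairs):
        out[(i, j)] = float(model.weights[c] / totals[i]) if totals[i] > 0 else 0.0
    return out
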