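"""Per-trace idealization with a Gaussian-emission hidden Markov model.

Each FRET trace is fitted individually (no stitching) with a K-state HMM whose
emissions are Gaussians on E.  Fitting is Baum–Welch EM (via hmmlearn) from
multiple randomized initializations — means seeded from data quantiles with
jitter — keeping the highest-likelihood model, canonicalized by ascending
mean.  Decoding is Viterbi with ties broken toward the lowest state index.
Model size can be selected per trace by BIC over a K range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .trace_io import FretTrace

VARIANCE_FLOOR = 1e-4  # in E^2; prevents EM collapse on noiseless data


class InsufficientFramesError(ValueError):
    """Trace too short for the requested number of states."""


class HmmFitError(RuntimeError):
    """All HMM fits failed."""


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM, canonicalized by ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    n_frames: int
    converged: bool = True
    variance_floored: bool = False

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def n_params(self) -> int:
        k = self.k
        return (k - 1) + k * (k - 1) + 2 * k

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_frames)

    def emission_logpdf(self, e: np.ndarray) -> np.ndarray:
        """(n_frames, K) log density of each frame under each state."""
        e = np.asarray(e, dtype=float)[:, None]
        var = self.sds[None, :] ** 2
        return -0.5 * (np.log(2 * np.pi * var) + (e - self.means[None, :]) ** 2 / var)

    def score(self, e: np.ndarray) -> float:
        """Forward-algorithm log-likelihood of an E series under this model."""
        logb = self.emission_logpdf(e)
        with np.errstate(divide="ignore"):
            log_t = np.log(self.transmat)
            alpha = np.log(self.startprob) + logb[0]
        for t in range(1, logb.shape[0]):
            alpha = logsumexp(alpha[:, None] + log_t, axis=0) + logb[t]
        return float(logsumexp(alpha))


@dataclass
class IdealizedPath:
    """Viterbi-decoded state sequence with fitted levels per frame."""

    trace_id: str
    states: np.ndarray  # int state index per frame
    levels: np.ndarray  # fitted mean of the decoded state per frame
    exposure: float
    e_raw: np.ndarray | None = field(default=None, repr=False)  # observed E
    model: HmmModel | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.states.size


def _as_series(fret: FretTrace | np.ndarray) -> np.ndarray:
    if isinstance(fret, FretTrace):
        return fret.e_valid
    return np.asarray(fret, dtype=float)


def fit_hmm(
    fret: FretTrace | np.ndarray,
    k: int,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    variance_floor: float = VARIANCE_FLOOR,
    init_means: np.ndarray | None = None,
    tied_variance: bool = False,
) -> HmmModel:
    """Fit a K-state Gaussian HMM to one trace by multi-start Baum–Welch EM.

    Initial means are data quantiles (first start), k-means centres (second),
    or jittered quantiles; ``init_means`` adds one further start from
    user-supplied level guesses — the classic camera-smFRET workflow seeds
    every trace with the same global state guesses, which rescues states the
    trace visits too briefly for data-driven initialization to see.  The
    highest-likelihood model is returned, canonicalized by ascending mean.
    Variances are floored at ``variance_floor`` (flagged when active) so
    noiseless traces cannot collapse the EM.

    ``tied_variance`` shares one emission variance across all states —
    appropriate for camera traces, whose additive read-out noise does not
    depend on the FRET state.  Per-state variances let a spare Gaussian
    absorb the frame-blur tail of a dense state instead of modelling a
    briefly-visited real state; the tied model removes that failure mode.
    """
    e = _as_series(fret)
    if k < 1:
        raise ValueError("k must be >= 1")
    if e.size < 5 * k:
        raise InsufficientFramesError(
            f"insufficient frames: {e.size} < {5 * k} for K={k}"
        )
    rng = np.random.default_rng(seed)

    if k == 1:
        mu = float(np.mean(e))
        var = max(float(np.var(e)), variance_floor)
        sd = np.sqrt(var)
        logl = float(
            np.sum(-0.5 * (np.log(2 * np.pi * var) + (e - mu) ** 2 / var))
        )
        return HmmModel(
            means=np.array([mu]),
            sds=np.array([sd]),
            transmat=np.ones((1, 1)),
            startprob=np.ones(1),
            log_likelihood=logl,
            n_frames=e.size,
            variance_floored=np.var(e) < variance_floor,
        )

    import logging

    from hmmlearn.hmm import GaussianHMM

    # the convergence monitor logs every sub-tolerance likelihood wiggle
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    x = e[:, None]
    quantiles = np.quantile(e, (np.arange(k) + 0.5) / k)
    spread = max(float(np.std(e)), 0.02)
    best: HmmModel | None = None

    extra = [np.sort(np.asarray(init_means, dtype=float))] if init_means is not None else []
    for start in range(n_starts + len(extra)):
        if start >= n_starts:
            means0 = extra[start - n_starts]
        elif start == 1:
            # k-means seeding separates briefly-visited states that plain
            # quantiles merge into their dense neighbours
            from sklearn.cluster import KMeans

            km = KMeans(
                n_clusters=k, n_init=3, random_state=int(rng.integers(2**31 - 1))
            ).fit(e[:, None])
            means0 = np.sort(km.cluster_centers_.ravel())
        else:
            means0 = quantiles.copy()
            if start > 0:
                means0 = np.sort(means0 + rng.normal(0.0, 0.25 * spread, k))
        model = GaussianHMM(
            n_components=k,
            covariance_type="tied" if tied_variance else "diag",
            n_iter=max_iter,
            tol=tol,
            min_covar=variance_floor,
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.startprob_ = np.full(k, 1.0 / k)
        model.transmat_ = np.full((k, k), 0.05 / (k - 1)) + np.eye(k) * (0.95 - 0.05 / (k - 1))
        model.transmat_ /= model.transmat_.sum(axis=1, keepdims=True)
        model.means_ = means0[:, None]
        var0 = max(spread**2 / k, variance_floor)
        model.covars_ = np.array([[var0]]) if tied_variance else np.full((k, 1), var0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
            logl = float(model.score(x))
        except Exception:
            continue
        if not np.isfinite(logl):
            continue
        floored = bool(np.any(model.covars_.ravel() <= variance_floor * 1.001))
        candidate = _canonicalize(model, logl, e.size, variance_floor, floored)
        if best is None or candidate.log_likelihood > best.log_likelihood:
            best = candidate
    if best is None:
        raise HmmFitError(f"all {n_starts} EM starts failed for K={k}")
    return best


def _canonicalize(
    model, logl: float, n_frames: int, variance_floor: float, floored: bool
) -> HmmModel:
    means = model.means_.ravel().copy()
    variances = np.maximum(model.covars_.reshape(-1), variance_floor)
    if variances.size == 1:  # tied covariance
        variances = np.full(means.size, variances[0])
    order = np.argsort(means)
    return HmmModel(
        means=means[order],
        sds=np.sqrt(variances[order]),
        transmat=model.transmat_[np.ix_(order, order)].copy(),
        startprob=model.startprob_[order].copy(),
        log_likelihood=logl,
        n_frames=n_frames,
        converged=bool(model.monitor_.converged),
        variance_floored=floored,
    )


def viterbi_path(model: HmmModel, fret: FretTrace | np.ndarray, trace_id: str | None = None) -> IdealizedPath:
    """Most-probable state sequence; deterministic, ties to the lowest index."""
    e = _as_series(fret)
    exposure = fret.exposure if isinstance(fret, FretTrace) else 1.0
    tid = trace_id or (fret.trace_id if isinstance(fret, FretTrace) else "trace")
    logb = model.emission_logpdf(e)
    n, k = logb.shape
    with np.errstate(divide="ignore"):
        log_t = np.log(model.transmat)
        delta = np.log(model.startprob) + logb[0]
    psi = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_t
        # argmax returns the first (lowest) index on ties
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(k)] + logb[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    return IdealizedPath(
        trace_id=tid,
        states=states,
        levels=model.means[states],
        exposure=exposure,
        e_raw=e,
        model=model,
    )


def prune_sparse_states(
    model: HmmModel,
    fret: FretTrace | np.ndarray,
    min_occupancy: float = 0.02,
    min_mean_run: float = 2.0,
    trace_id: str | None = None,
) -> tuple[HmmModel, IdealizedPath]:
    """Iteratively drop artefact states and re-decode.

    Fixed-K fits of traces that visit fewer states park spare Gaussians on
    frame-blur artefacts — the single camera frames that time-average a
    mid-frame transition to an intermediate apparent E.  Such states are
    visited only in isolated frames, so they are recognized by a mean Viterbi
    run length below ``min_mean_run`` frames (genuine states dwell for
    exponential, multi-frame runs) or by occupancy below ``min_occupancy``.
    Removal renormalizes the transition matrix over the surviving states.
    Returns the (possibly reduced) model and its decoded path.
    """
    current = model
    while True:
        path = viterbi_path(current, fret, trace_id=trace_id)
        if current.k <= 1:
            return current, path
        occ = np.bincount(path.states, minlength=current.k) / path.n_frames
        boundaries = np.flatnonzero(np.diff(path.states) != 0)
        run_states = path.states[np.concatenate(([0], boundaries + 1))]
        n_runs = np.bincount(run_states, minlength=current.k)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_run = occ * path.n_frames / n_runs
        blur_like = (n_runs == 0) | (mean_run < min_mean_run) | (occ < min_occupancy)
        if not blur_like.any():
            return current, path
        # drop the worst offender first (shortest mean run, then occupancy)
        score = np.where(blur_like, np.nan_to_num(mean_run, nan=0.0) + occ, np.inf)
        drop = int(np.argmin(score))
        keep = np.array([i for i in range(current.k) if i != drop])
        transmat = current.transmat[np.ix_(keep, keep)]
        transmat = transmat / transmat.sum(axis=1, keepdims=True)
        startprob = current.startprob[keep]
        total = startprob.sum()
        startprob = startprob / total if total > 0 else np.full(keep.size, 1.0 / keep.size)
        current = HmmModel(
            means=current.means[keep],
            sds=current.sds[keep],
            transmat=transmat,
            startprob=startprob,
            log_likelihood=current.log_likelihood,
            n_frames=current.n_frames,
            converged=current.converged,
            variance_floored=current.variance_floored,
        )


def select_k(
    fret: FretTrace | np.ndarray,
    k_range: tuple[int, int] = (1, 10),
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    tied_variance: bool = False,
) -> tuple[HmmModel, dict[int, float]]:
    """Fit HMMs over a K range and return the BIC-minimal model.

    BIC = −2·logL + p·ln(n_frames) with p = (K−1) + K(K−1) + 2K.  Candidate K
    with too few frames are skipped; if every fit fails a diagnostic error is
    raised.
    """
    lo, hi = k_range
    if lo < 1 or hi > 10 or lo > hi:
        raise ValueError("k_range must lie within 1..10")
    rng = np.random.default_rng(seed)
    bics: dict[int, float] = {}
    models: dict[int, HmmModel] = {}
    failures: dict[int, str] = {}
    for k in range(lo, hi + 1):
        try:
            m = fit_hmm(
                fret, k, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=rng,
                tied_variance=tied_variance,
            )
        except (InsufficientFramesError, HmmFitError) as err:
            failures[k] = str(err)
            continue
        models[k] = m
        bics[k] = m.bic
    if not models:
        raise HmmFitError(f"all K failed: {failures}")
    best_k = min(bics, key=lambda k: (bics[k], k))
    return models[best_k], bics


def idealize(
    fret: FretTrace,
    k: int | None = None,
    k_range: tuple[int, int] = (1, 10),
    **kwargs,
) -> IdealizedPath:
    """Convenience: fit (fixed K or BIC-selected) then Viterbi-decode."""
    if k is not None:
        model = fit_hmm(fret, k, **kwargs)
    else:
        model, _ = select_k(fret, k_range=k_range, **kwargs)
    return viterbi_path(model, fret)
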