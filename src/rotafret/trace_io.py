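"""Trace containers, file round-trip, FRET conversion and quality filtering.

Traces travel as per-frame donor/acceptor count series on a uniform time grid.
Two on-disk dialects are supported: a delimited long-format table
(columns ``trace_id, frame, time_s, donor, acceptor``) and an HDF5 container
(one group per trace, channel datasets plus an ``exposure`` attribute).

FRET efficiency is computed as the corrected ratio

    E = (I_A − β·I_D − bg_A) / ((I_A − β·I_D − bg_A) + γ·(I_D − bg_D))

which reduces to the uncorrected proximity ratio at the defaults
γ = 1, β = 0, bg = 0.  Frames with a non-positive denominator are masked
invalid, never clipped or interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]


class SchemaError(ValueError):
    """A trace table is missing required columns or malformed."""


@dataclass
class IntensityTrace:
    """Per-frame two-channel counts on a uniform grid starting at t = 0."""

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    exposure: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise SchemaError("donor/acceptor must be equal-length 1D series")
        if self.exposure <= 0:
            raise SchemaError("exposure must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.exposure

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def truncated(self, stop: int) -> "IntensityTrace":
        out = IntensityTrace(
            trace_id=self.trace_id,
            donor=self.donor[:stop].copy(),
            acceptor=self.acceptor[:stop].copy(),
            exposure=self.exposure,
            meta=dict(self.meta),
        )
        return out


@dataclass
class FretTrace:
    """Per-frame FRET efficiency with a validity mask.

    ``e`` is defined only where ``valid``; invalid frames (non-positive
    denominator in the correction formula) hold NaN.
    """

    trace_id: str
    e: np.ndarray
    valid: np.ndarray
    exposure: float

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.e.shape != self.valid.shape:
            raise SchemaError("e and valid must have equal length")
        if not np.all(np.isfinite(self.e[self.valid])):
            raise SchemaError("valid frames must hold finite E")

    @property
    def n_frames(self) -> int:
        return self.e.size

    @property
    def e_valid(self) -> np.ndarray:
        return self.e[self.valid]


def compute_fret(
    trace: IntensityTrace,
    gamma: float = 1.0,
    beta: float = 0.0,
    bg_donor: float = 0.0,
    bg_acceptor: float = 0.0,
) -> FretTrace:
    """Convert a two-channel trace to FRET efficiency (proximity ratio by default)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    fa = trace.acceptor - beta * trace.donor - bg_acceptor
    fd = trace.donor - bg_donor
    denom = fa + gamma * fd
    valid = denom > 0
    e = np.full(trace.n_frames, np.nan)
    np.divide(fa, denom, out=e, where=valid)
    return FretTrace(trace_id=trace.trace_id, e=e, valid=valid, exposure=trace.exposure)


# ---------------------------------------------------------------------------
# file round trip


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": t.trace_id,
                    "frame": np.arange(t.n_frames),
                    "time_s": t.frame_times,
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[IntensityTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    traces = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        group = group.sort_values("frame")
        times = group["time_s"].to_numpy(dtype=float)
        if times.size > 1:
            spacing = np.diff(times)
            if not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
                warnings.warn(
                    f"trace {trace_id!r}: non-uniform frame spacing; trace rejected",
                    stacklevel=2,
                )
                continue
            exposure = float(spacing[0])
        else:
            exposure = float(times[0]) if times[0] > 0 else 1.0
        traces.append(
            IntensityTrace(
                trace_id=str(trace_id),
                donor=group["donor"].to_numpy(dtype=float),
                acceptor=group["acceptor"].to_numpy(dtype=float),
                exposure=exposure,
            )
        )
    return traces


def write_traces(traces: list[IntensityTrace], path: str | Path, format: str | None = None) -> None:
    """Write traces as a delimited table (``csv``) or HDF5 container (``h5``)."""
    path = Path(path)
    fmt = format or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        # %.17g guarantees binary-lossless float round trip
        traces_to_frame(traces).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "h5":
        import h5py

        with h5py.File(path, "w") as fh:
            for t in traces:
                g = fh.create_group(t.trace_id)
                g.create_dataset("donor", data=t.donor)
                g.create_dataset("acceptor", data=t.acceptor)
                g.attrs["exposure"] = t.exposure
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_traces(path: str | Path, format: str | None = None) -> list[IntensityTrace]:
    path = Path(path)
    fmt = format or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        return frame_to_traces(pd.read_csv(path, float_precision="round_trip"))
    if fmt == "h5":
        import h5py

        traces = []
        with h5py.File(path, "r") as fh:
            for trace_id in fh:
                g = fh[trace_id]
                for col in ("donor", "acceptor"):
                    if col not in g:
                        raise SchemaError(f"missing required column(s): {col}")
                traces.append(
                    IntensityTrace(
                        trace_id=trace_id,
                        donor=g["donor"][:],
                        acceptor=g["acceptor"][:],
                        exposure=float(g.attrs["exposure"]),
                    )
                )
        return traces
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterCriteria:
    """Trace-level quality criteria.

    min_length: minimum frames after bleach truncation.
    min_total_intensity: minimum mean total counts; ``None`` uses half the
        dataset median (adaptive).
    min_acceptor_fraction: reject traces whose mean acceptor share of the
        total counts falls below this (the zero-FRET donor-only nuisance
        population carries no acceptor signal); ``None`` disables.
    max_e_excursion: reject traces where >5% of frames have proximity ratio
        outside [−x, 1+x]; ``None`` disables.
    truncate_at_bleach: cut each trace at the first detected single-step
        donor or acceptor photobleach.
    require_single_bleach_step: reject traces with no detectable bleach step
        (used to enforce single-molecule character).
    bleach_dark_sd: multiple of the per-channel noise SD (estimated from
        frame-to-frame differences) below which a channel counts as dark.
    bleach_window: window (frames) of the rolling median used for the
        dark-tail bleach detection.
    """

    min_length: int = 100
    min_total_intensity: float | None = None
    min_acceptor_fraction: float | None = 0.05
    max_e_excursion: float | None = None
    truncate_at_bleach: bool = True
    require_single_bleach_step: bool = False
    bleach_dark_sd: float = 3.0
    bleach_window: int = 5


@dataclass
class FilterResult:
    kept: list[IntensityTrace]
    rejected: list[tuple[str, str]]  # (trace_id, reason)

    @property
    def reasons(self) -> dict[str, str]:
        return dict(self.rejected)


def _noise_sd(x: np.ndarray) -> float:
    """Robust per-frame noise SD from lag-1 differences (MAD-based)."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)


def detect_bleach_step(
    x: np.ndarray, dark_sd: float = 3.0, window: int = 5
) -> int | None:
    """First frame of a single-step photobleach in a signal, or None.

    Single-step photobleaching leaves the channel at background for the rest
    of the trace, so the bleach frame is the start of the terminal run where
    the forward rolling median sits below the dark level,
    max(``dark_sd`` x noise SD, 10% of the bright-signal scale).  The
    dark-tail signature separates a bleach from an anti-correlated FRET
    transition (same instantaneous step, no dark tail) and catches bleaches
    out of low-FRET states whose step is small.
    """
    n = x.size
    w = window
    if n < 2 * w + 2:
        return None
    sigma = _noise_sd(x)
    if sigma <= 0:
        sigma = 1e-12
    dark_level = max(dark_sd * sigma, 0.1 * float(np.percentile(x, 95)))
    # forward-looking rolling median; the final frames inherit the tail value
    rm = np.empty(n)
    for t in range(n - w):
        rm[t] = np.median(x[t : t + w])
    rm[n - w :] = rm[n - w - 1]
    dark = rm < dark_level
    if not dark[-1]:
        return None
    run_start = n - 1
    while run_start > 0 and dark[run_start - 1]:
        run_start -= 1
    if run_start == 0:
        return 0  # dark throughout (no signal in this channel)
    if n - run_start < 2 * w:
        return None  # tail too short to call
    return run_start


def find_bleach_frame(trace: IntensityTrace, criteria: FilterCriteria) -> int | None:
    """First detected bleach frame (donor via total counts, acceptor via its channel).

    An acceptor channel dark from frame 0 is the donor-only population, not a
    bleach, and is left to the acceptor-fraction criterion.
    """
    candidates = []
    for signal, channel in ((trace.total, "total"), (trace.acceptor, "acceptor")):
        t = detect_bleach_step(signal, criteria.bleach_dark_sd, criteria.bleach_window)
        if t is not None and not (channel == "acceptor" and t == 0):
            candidates.append(t)
    return min(candidates) if candidates else None


def filter_traces(
    traces: list[IntensityTrace], criteria: FilterCriteria | None = None
) -> FilterResult:
    """Apply trace-level quality filters; every rejection carries a reason.

    Deterministic and idempotent: bleach-truncated traces pass unchanged on a
    second pass.  The adaptive intensity cutoff (half the median of per-trace
    median totals) is recomputed per call; idempotence of that criterion
    assumes the usual bimodal bright/dim split where the half-median cutoff
    stays below the kept population — pass an explicit
    ``min_total_intensity`` for a set-independent guarantee.
    """
    criteria = criteria or FilterCriteria()
    kept: list[IntensityTrace] = []
    rejected: list[tuple[str, str]] = []

    min_intensity = criteria.min_total_intensity
    if min_intensity is None and traces:
        medians = [float(np.median(t.total)) for t in traces]
        min_intensity = 0.5 * float(np.median(medians))

    for trace in traces:
        work = trace
        bleach = find_bleach_frame(work, criteria) if criteria.truncate_at_bleach else None
        if criteria.require_single_bleach_step and bleach is None:
            rejected.append((trace.trace_id, "no_bleach"))
            continue
        if bleach is not None:
            work = work.truncated(bleach)
            work.meta["bleach_frame"] = bleach
        if work.n_frames < criteria.min_length:
            rejected.append((trace.trace_id, "short"))
            continue
        if min_intensity is not None and float(np.mean(work.total)) < min_intensity:
            rejected.append((trace.trace_id, "dim"))
            continue
        if criteria.min_acceptor_fraction is not None:
            tot = float(np.mean(work.total))
            frac = float(np.mean(work.acceptor)) / tot if tot > 0 else 0.0
            if frac < criteria.min_acceptor_fraction:
                rejected.append((trace.trace_id, "donor_only"))
                continue
        if criteria.max_e_excursion is not None:
            e = compute_fret(work).e
            x = criteria.max_e_excursion
            bad = np.mean((e < -x) | (e > 1 + x) | ~np.isfinite(e))
            if bad > 0.05:
                rejected.append((trace.trace_id, "excursion"))
                continue
        kept.append(work)
    return FilterResult(kept=kept, rejected=rejected)
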