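"""End-to-end orchestration: simulate → FRET → filter → idealize → TDP → rates.

A run is fully determined by its configuration and master seed.  Stage seeds
are derived from the master seed by a counter scheme
(``SeedSequence((master_seed, stage_index))``), so any stage can be re-run in
isolation; the indices are recorded in the report provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dwell_kinetics import (
    BootstrapResult,
    DwellDistribution,
    RateEstimate,
    bootstrap_rates,
    choose_fit,
    collect_dwells,
    scale_by_cluster_weight,
    with_bootstrap_errors,
)
from .hmm_segmentation import (
    HmmFitError,
    IdealizedPath,
    InsufficientFramesError,
    fit_hmm,
    prune_sparse_states,
    select_k,
    viterbi_path,
)
from .synthetic_traces import (
    PRESET_STATE_MEANS,
    STATE_NAMES,
    EmissionModel,
    KineticScheme,
    generate_dataset,
)
from .trace_io import FilterCriteria, compute_fret, filter_traces, traces_to_frame
from .transition_analysis import (
    ClusteringError,
    branching_weights,
    cluster_tdp,
    extract_transitions,
    transition_counts,
)

logger = logging.getLogger("rotafret.pipeline")

_STAGE_SEEDS = {"simulate": 0, "idealize": 1, "cluster": 2, "bootstrap": 3}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((master_seed, _STAGE_SEEDS[stage]))


@dataclass
class RunConfig:
    """Configuration of a full analysis run (see docs/methods.md for defaults)."""

    preset: str = "sin37"
    n_traces: int = 200
    duration: float = 25.0
    master_seed: int = 0
    donor_only_fraction: float = 0.1
    # idealization
    idealize_mode: str = "fixed"  # "fixed" (K states per trace) or "select" (per-trace BIC)
    fixed_k: int = 4
    min_delta_e: float = 0.05  # diagonal exclusion for TDP records
    prune_min_occupancy: float = 0.02  # drop fitted states below this occupancy
    prune_min_mean_run: float = 2.0  # frames; drop blur-like states (0 disables)
    idealize_k_range: tuple[int, int] = (1, 5)
    idealize_n_starts: int = 3
    idealize_tol: float = 1e-5
    tied_variance: bool = True  # camera noise is state-independent
    # TDP clustering
    tdp_k_range: tuple[int, int] = (1, 10)
    tdp_n_init: int = 30
    # TDP record coordinates: fitted state levels (default) or observed mean
    # E over each dwell ("dwell_mean"; heterogeneous spread, display only)
    tdp_level_source: str = "fitted"
    # kinetics
    n_boot: int = 100
    min_dwells: int = 5
    dwell_dead_time: str | float = "frame"  # "frame" = one exposure; or seconds
    run_kinetics: bool = True
    # corrections / filtering
    gamma: float = 1.0
    beta: float = 0.0
    bg_donor: float = 0.0
    bg_acceptor: float = 0.0
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    # custom scheme/emission overrides (None → preset defaults)
    scheme: KineticScheme | None = None
    emission: EmissionModel | None = None
    out_dir: str | None = None

    def resolved_scheme(self) -> KineticScheme:
        return self.scheme if self.scheme is not None else KineticScheme.preset(self.preset)

    def resolved_emission(self) -> EmissionModel:
        return self.emission if self.emission is not None else EmissionModel.preset(self.preset)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TransitionRate:
    """Per-transition kinetic summary for the report."""

    pair: tuple[int, int]
    labels: tuple[str, str]
    n_dwells: int
    a1: float
    k1: float
    a2: float
    k2: float
    k_av: float  # branching-weight scaled, 1/s
    d_k_av: float  # printed-formula propagation, scaled
    k_av_sd_boot: float  # bootstrap SD of the unscaled k_av
    branching_weight: float
    n_components: int


@dataclass
class RunReport:
    """Result of one pipeline run; regenerable from config + master seed."""

    k_opt: int
    levels: np.ndarray
    level_sds: np.ndarray
    state_labels: list[str]
    transition_fractions: dict[tuple[int, int], float]
    rates: dict[tuple[int, int], TransitionRate]
    counts: dict[str, int]
    kinetics_skipped_reason: str | None
    bic_by_k: dict[int, float]
    provenance: dict

    def rate_for(self, from_label: str, to_label: str) -> TransitionRate | None:
        for rate in self.rates.values():
            if rate.labels == (from_label, to_label):
                return rate
        return None

    def to_json_dict(self) -> dict:
        return {
            "k_opt": self.k_opt,
            "levels": [round(float(v), 4) for v in self.levels],
            "level_sds": [round(float(v), 4) for v in self.level_sds],
            "state_labels": self.state_labels,
            "transition_fractions": {
                f"{i}->{j}": round(f, 4) for (i, j), f in self.transition_fractions.items()
            },
            "rates": {
                f"{r.labels[0]}->{r.labels[1]}": {
                    "n_dwells": r.n_dwells,
                    "A1": round(r.a1, 4),
                    "k1": round(r.k1, 4),
                    "A2": round(r.a2, 4),
                    "k2": round(r.k2, 4),
                    "k_av": round(r.k_av, 4),
                    "dk_av": round(r.d_k_av, 4),
                    "k_av_sd_boot": round(r.k_av_sd_boot, 4),
                    "weight": round(r.branching_weight, 4),
                    "n_components": r.n_components,
                }
                for r in self.rates.values()
            },
            "counts": self.counts,
            "kinetics_skipped_reason": self.kinetics_skipped_reason,
            "bic_by_k": {str(k): round(v, 2) for k, v in self.bic_by_k.items()},
            "provenance": self.provenance,
        }


def _state_labels(levels: np.ndarray, preset: str) -> list[str]:
    """Map sorted recovered levels to the cycle's state names when K matches."""
    if preset in PRESET_STATE_MEANS and levels.size == len(PRESET_STATE_MEANS[preset]):
        order = np.argsort(PRESET_STATE_MEANS[preset])
        return [STATE_NAMES[i] for i in order]
    return [f"S{i + 1}" for i in range(levels.size)]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full seeded analysis chain and assemble the report."""
    scheme = config.resolved_scheme()
    emission = config.resolved_emission()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    sim_seed = int(stage_seed(config.master_seed, "simulate").generate_state(1)[0] % 2**31)
    dataset = generate_dataset(
        scheme,
        emission,
        config.n_traces,
        config.duration,
        seed=sim_seed,
        donor_only_fraction=config.donor_only_fraction,
    )
    logger.info("simulated %d traces of %.1f s", config.n_traces, config.duration)

    filtered = filter_traces(dataset.traces, config.filter_criteria)
    logger.info("filter: kept %d, rejected %d", len(filtered.kept), len(filtered.rejected))

    frets = [
        compute_fret(t, config.gamma, config.beta, config.bg_donor, config.bg_acceptor)
        for t in filtered.kept
    ]

    ideal_rng = np.random.default_rng(stage_seed(config.master_seed, "idealize"))

    # HaMMy-style shared initial guesses: one k-means on the pooled E
    # histogram seeds an extra EM start for every trace, so states a given
    # trace visits only briefly are still offered to its fit
    global_init = None
    if config.idealize_mode == "fixed" and frets:
        from sklearn.cluster import KMeans

        pooled = np.concatenate([f.e_valid for f in frets])
        if pooled.size > 50_000:
            pooled = pooled[:: pooled.size // 50_000 + 1]
        km = KMeans(
            n_clusters=config.fixed_k,
            n_init=5,
            random_state=int(ideal_rng.integers(2**31 - 1)),
        ).fit(pooled[:, None])
        global_init = np.sort(km.cluster_centers_.ravel())

    paths: list[IdealizedPath] = []
    idealize_failures = 0
    for fret in frets:
        try:
            if config.idealize_mode == "fixed":
                model = fit_hmm(
                    fret,
                    config.fixed_k,
                    n_starts=config.idealize_n_starts,
                    tol=config.idealize_tol,
                    seed=ideal_rng,
                    init_means=global_init,
                    tied_variance=config.tied_variance,
                )
            else:
                model, _ = select_k(
                    fret,
                    k_range=config.idealize_k_range,
                    n_starts=config.idealize_n_starts,
                    tol=config.idealize_tol,
                    seed=ideal_rng,
                    tied_variance=config.tied_variance,
                )
        except (InsufficientFramesError, HmmFitError) as err:
            logger.warning("idealization failed for %s: %s", fret.trace_id, err)
            idealize_failures += 1
            continue
        if config.prune_min_mean_run > 0 or config.prune_min_occupancy > 0:
            _, path = prune_sparse_states(
                model,
                fret,
                min_occupancy=config.prune_min_occupancy,
                min_mean_run=config.prune_min_mean_run,
            )
        else:
            path = viterbi_path(model, fret)
        paths.append(path)

    records = extract_transitions(
        paths, min_delta_e=config.min_delta_e, level_source=config.tdp_level_source
    )
    counts = {
        "traces_in": config.n_traces,
        "traces_kept": len(filtered.kept),
        "traces_rejected": len(filtered.rejected),
        "idealize_failures": idealize_failures,
        "n_transitions": len(records),
    }
    provenance = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seed_indices": dict(_STAGE_SEEDS),
        "version": __version__,
        "preset": config.preset,
    }

    if len(records) < 10:
        report = RunReport(
            k_opt=1,
            levels=np.array([float(np.mean(np.concatenate([f.e_valid for f in frets])))])
            if frets
            else np.array([]),
            level_sds=np.array([0.0]) if frets else np.array([]),
            state_labels=["S1"],
            transition_fractions={},
            rates={},
            counts=counts,
            kinetics_skipped_reason="fewer than 10 transitions",
            bic_by_k={},
            provenance=provenance,
        )
        _persist(out_dir, dataset, records, report)
        return report

    cluster_seed = np.random.default_rng(stage_seed(config.master_seed, "cluster"))
    model = cluster_tdp(
        records,
        k_range=config.tdp_k_range,
        n_init=config.tdp_n_init,
        seed=cluster_seed,
    )
    fractions = transition_counts(model, records)
    labels = _state_labels(model.levels, config.preset)
    logger.info("TDP clustering: K_opt=%d levels=%s", model.k, np.round(model.levels, 3))

    rates: dict[tuple[int, int], TransitionRate] = {}
    skipped_reason = None
    if not config.run_kinetics:
        skipped_reason = "kinetics disabled in config"
    elif model.k == 1:
        skipped_reason = "single-state model: no transitions to fit"
    else:
        assignment = model.assign(records)
        dwells = collect_dwells(records, assignment, model)
        weights = branching_weights(model)
        boot_rng = np.random.default_rng(stage_seed(config.master_seed, "bootstrap"))
        dead_time = (
            emission.exposure
            if config.dwell_dead_time == "frame"
            else float(config.dwell_dead_time)
        )
        for pair, dist in sorted(dwells.items()):
            if dist.n < config.min_dwells:
                continue
            chosen, _, _ = choose_fit(dist, dead_time)
            boot = bootstrap_rates(
                dist, chosen.n_components, config.n_boot, boot_rng, dead_time
            )
            fit = with_bootstrap_errors(chosen, boot)
            estimate = scale_by_cluster_weight(fit, weights[pair])
            i, j = pair
            rates[pair] = TransitionRate(
                pair=pair,
                labels=(labels[i], labels[j]),
                n_dwells=dist.n,
                a1=fit.a1,
                k1=fit.k1,
                a2=fit.a2,
                k2=fit.k2 if np.isfinite(fit.k2) else 0.0,
                k_av=estimate.k_av,
                d_k_av=estimate.d_k_av,
                k_av_sd_boot=boot.sd_k_av,
                branching_weight=weights[pair],
                n_components=chosen.n_components,
            )
        counts["n_dwell_pairs_fitted"] = len(rates)

    report = RunReport(
        k_opt=model.k,
        levels=model.levels,
        level_sds=model.level_sds(),
        state_labels=labels,
        transition_fractions=fractions,
        rates=rates,
        counts=counts,
        kinetics_skipped_reason=skipped_reason,
        bic_by_k=model.bic_by_k,
        provenance=provenance,
    )
    _persist(out_dir, dataset, records, report)
    return report


def _persist(out_dir, dataset, records, report) -> None:
    if out_dir is None:
        return
    traces_to_frame(dataset.traces).to_csv(out_dir / "traces.csv", index=False)
    dataset.ground_truth_table().to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "e_before": r.e_before,
                "e_after": r.e_after,
                "dwell_before": r.dwell_before,
                "truncated_left": r.truncated_left,
                "truncated_right": r.truncated_right,
            }
            for r in records
        ]
    ).to_csv(out_dir / "transitions.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)


def compare_to_reference(
    report: RunReport, reference: pd.DataFrame
) -> pd.DataFrame:
    """Deviation summary of report levels/rates vs a reference table.

    ``reference`` columns: kind ("level"|"rate"), key (state label or
    "from->to"), value, sd (optional), tol (optional absolute tolerance).
    Missing keys are listed with NaN deviations, not fatal.
    """
    rows = []
    label_to_level = dict(zip(report.state_labels, report.levels))
    for _, ref in reference.iterrows():
        kind, key, value = ref["kind"], ref["key"], float(ref["value"])
        sd = float(ref["sd"]) if "sd" in ref and pd.notna(ref.get("sd")) else None
        tol = float(ref["tol"]) if "tol" in ref and pd.notna(ref.get("tol")) else None
        got = None
        if kind == "level":
            got = label_to_level.get(key)
        elif kind == "rate":
            src, dst = key.split("->")
            rate = report.rate_for(src, dst)
            got = rate.k_av if rate is not None else None
        if got is None:
            rows.append(
                {"kind": kind, "key": key, "reference": value, "observed": np.nan,
                 "deviation": np.nan, "sd_scaled": np.nan, "within_tol": False,
                 "missing": True}
            )
            continue
        dev = got - value
        rows.append(
            {
                "kind": kind,
                "key": key,
                "reference": value,
                "observed": got,
                "deviation": dev,
                "sd_scaled": dev / sd if sd else np.nan,
                "within_tol": abs(dev) <= tol if tol is not None else np.nan,
                "missing": False,
            }
        )
    return pd.DataFrame(rows)
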