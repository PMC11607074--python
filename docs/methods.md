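# Methods

`rotafret` re-implements, as a tested package, the camera-based (TIRF)
single-molecule FRET analysis used to demonstrate subunit rotation by serine
recombinases, together with the closed-form photophysics and the
accessible-volume structural modelling that frame it.  This note records the
models, the defaults and why, and what the synthetic data can and cannot
establish.

## The kinetic model

Strand exchange at a cleaved synaptic complex is modelled as a continuous-time
Markov chain on the linear chain

```
lnr  ⇌(k_cle / k_lig)  cnr  ⇌(k_rec / k_non_rec)  cr  ⇌(k_lig / k_cle)  lr
```

where lnr/cnr are the ligated/cleaved non-recombinant intermediates, cr/lr
their recombinant counterparts, and k_rec / k_non_rec are the forward and
reverse 180° subunit-rotation rates.  Each state has an apparent FRET
efficiency; the presets carry the published values:

| preset    | E(lnr) | E(cnr) | E(cr) | E(lr) | k_rec (1/s) | k_non_rec (1/s) |
|-----------|--------|--------|-------|-------|-------------|-----------------|
| `sin37`   | 0.16   | 0.29   | 0.50  | 0.77  | 0.86        | 0.48            |
| `sin37_mg`| 0.13   | 0.29   | 0.53  | 0.79  | 0.86*       | 0.48*           |
| `sin21`   | 0.17   | 0.34   | 0.54  | 0.78  | 0.86*       | 0.48*           |
| `tn3`     | 0.12   | 0.31   | 0.54  | 0.73  | 1.14        | 0.41            |

Values marked * are placeholders (rotation rates for these conditions are not
published at main-text precision); the cleavage/ligation rates default to a
documented placeholder of 1.0 /s in all presets and are plain configuration
values.

## Synthetic traces

State paths are exact Gillespie realizations (exponential waiting times at
the total exit rate, successors proportional to individual rates), started
from the stationary distribution of the rate matrix by default.  Rendering
emulates an EMCCD camera at 50 ms exposure over ~25 s:

* **frame blurring** — each frame carries the time-weighted mean E of the
  path segments overlapping its exposure window, which is what produces the
  intermediate-E single frames and the "skipped state" artefacts of real
  camera data;
* **intensity model** — total intensity 1000 counts/frame split
  donor/acceptor by E; additive Gaussian noise of 30 counts per channel
  (per-frame σ(E) ≈ 0.04, consistent with the published state SDs of
  0.02–0.04), Poisson noise optional;
* **photobleaching** — independent exponential clocks (defaults: acceptor
  0.01 /s, donor 0.005 /s); after acceptor bleach the full intensity appears
  in the donor channel, after donor bleach both channels drop to background.
  Post-bleach frames are retained so the downstream truncation logic is
  testable;
* **nuisance population** — a configurable fraction (0.1 in the presets) of
  zero-FRET donor-only traces.

What the generator does **not** emulate: acceptor blinking, spectral
crosstalk beyond the configurable β, background drift, multi-step bleaching
of aggregates, and intensity heterogeneity between molecules.  Passing the
recovery tests therefore shows the estimator chain is correct and unbiased
under its own assumptions at realistic signal-to-noise, not that it is robust
to every artefact of real recordings.

## Trace processing

FRET efficiency defaults to the uncorrected proximity ratio
E = I_A / (I_A + I_D); γ, β and backgrounds are exposed because the camera
analysis operates on apparent E.  Frames with a non-positive denominator are
masked, never interpolated.

Filtering is declared, deterministic and overridable: minimum 100 frames
after truncation, mean total intensity above half the dataset median, mean
acceptor share above 5% (removes the donor-only population), and bleach
truncation.  Bleach detection uses the *dark-tail* signature — the terminal
run where a channel's rolling median stays below max(3×noise SD, 10% of the
bright scale) — on the acceptor channel (acceptor bleach) and the summed
channels (donor bleach).  A step detector cannot do this job: an
anti-correlated FRET transition has the same instantaneous step as an
acceptor bleach, and a bleach out of a low-FRET state has a step smaller
than any safe threshold.

## Idealization

Each trace is fitted individually (no stitching) with a Gaussian-emission
HMM by multi-start Baum–Welch EM and decoded by Viterbi (ties to the lowest
state index).  Defaults: 4 states per trace, tied emission variance,
variance floor 1e-4 E², n_starts 10 (library) / 3 (pipeline), tol 1e-6,
max 1000 iterations.  Three choices matter and are deliberate:

* **fixed K = 4 per trace** (per-trace BIC selection is available): selecting
  K per trace systematically merges briefly-visited states into intermediate
  levels, which later surface as phantom TDP states;
* **tied variance**: camera read-out noise does not depend on the FRET
  state.  With free per-state variances the ML solution for a trace that
  visits a state only briefly is to merge it and spend the spare Gaussian on
  the frame-blur tail of a dense state; the tied model removes this failure
  mode;
* **initialization**: quantile seeds, a k-means seed, jittered quantiles,
  plus one start from k-means levels of the pooled dataset histogram — the
  same role as the global initial guesses the classic camera-smFRET tools
  ask the user for.

After decoding, states visited only in isolated frames (mean run length
< 2 frames, or occupancy < 2%) are pruned and the trace re-decoded: genuine
states dwell in exponential multi-frame runs, while spare Gaussians that
latched onto mid-transition blur frames are visited one frame at a time.

BIC for K selection is −2·logL + p·ln(n_frames) with
p = (K−1) + K(K−1) + 2K.

## Transition density plot and clustering

Every state change yields a record (E_before, E_after, preceding dwell).
Records with |ΔE| < 0.05 are dropped as flicker between near-duplicate
levels (runs are merged across the dropped boundary so dwells stay
contiguous); first-run dwells are left-censored and flagged.  The record
coordinate is the fitted state level; the observed dwell-mean coordinate is
available (`level_source="dwell_mean"`) but its dwell-length-dependent
spread is a scale mixture that the cluster model misfits, so it is not the
default.

The number of FRET states is inferred by fitting the raw transition points
with a constrained mixture of K(K−1) isotropic 2D Gaussians — the cluster
centres are the Cartesian pairs of K shared levels; free parameters are the
K levels, K(K−1)−1 weights and one variance per cluster (floored at
1e-4 E²) — by EM over K = 1..10 with 30 seeded initializations each, keeping
the best by likelihood.  Each initialization runs a 30-iteration burn-in and
only the best is converged fully (tol 1e-7, max 200 iterations); the shared
levels update by precision-weighted averaging over all clusters that use
them on either axis.  K = 1 is the no-transition null: a single broad
isotropic background component (3 parameters).  Model choice is BIC
(−2·logL + p·ln(n_records), p = K + (K(K−1)−1) + K(K−1)); ties go to the
smaller K.  The Gaussian-convolved TDP grid is produced for display only.

## Dwell-time kinetics

Dwells pool by maximum-responsibility cluster, censored dwells excluded,
pairs with fewer than 5 dwells flagged and skipped.  The unbinned empirical
CDF is fitted with mono- and biexponential decays
F(t) = 1 − A₁e^(−k₁(t−t₀)) − A₂e^(−k₂(t−t₀)), A₁+A₂ = 1, where t₀ is the
one-frame dead time: dwells shorter than a frame are unobservable, and by
memorylessness the observed distribution is the shifted exponential.
Without the shift, recovered rates are biased low by roughly (1 − k·t₀).
Model order is chosen by BIC on the dwell sample; both fits are reported.
Parameter uncertainties come from a bootstrap over dwells (100 resamples,
reported as 3×SD).

Each transition's rate is the cluster-weight-scaled weighted-average rate:
k(i→j) = w(i→j|i) · k_av, where w(i→j|i) is the branching fraction of the
cluster weight among all departures from state i (so competing exits re-sum
to the state's total exit rate) and

    k_av = 1 / (A₁/k₁ + A₂/k₂).

The error combination is implemented verbatim from its published form:
M = A₁/k₁, ΔM = M·sqrt((ΔA₁/A₁)² + (Δk₁/k₁)²) (N, ΔN analogously) and
Δk_av = sqrt(ΔM² + ΔN²).  As printed this carries units of time, not rate;
it is reproduced exactly (mode `"printed"`) with a dimensionally consistent
alternative Δk_av = k_av²·sqrt(ΔM² + ΔN²) (mode `"propagated"`, the
first-order error of 1/(M+N)) clearly labelled as not the published recipe.

Expected behaviour of the estimator on the presets: state levels recover to
±0.01, K_opt = 4 in essentially all replicates at 120–200 traces, and the
cnr→cr rotation rate to within a few percent (residual biases — Viterbi
suppression of one-frame dwells, skipped-state misassignment — are inside
the bootstrap error at 200 traces).

## Förster conversions

R = R₀·((1−E)/E)^(1/6) and its inverse, with the published Förster radii
(Atto532/Cy5 67.4 Å, Cy3B/Cy5 67.0 Å, Alexa488/Cy5 51.4 Å).  The shipped
state table reproduces the published distance column from the printed E and
R₀ and *flags* rows where the two printed numbers disagree by more than
0.1 Å (two such rows exist, both explained by rounding of E; the burst-mode
lr row printing E = 0.50 with R_DA = 52.8 Å at R₀ = 51.4 Å back-computes to
E = 0.46) instead of silently matching them.  Burst-analysis reference
lines: E = 1 − τ_DA/τ_D (τ_D = 4.0 ns) and the Perrin line
r = r₀/(1 + τ/ρ) (r₀ = 0.375, ρ = 0.35 ns).

## Accessible volumes and the rotation scan

The AV of a tethered dye is computed on a cubic grid (default 1.0 Å, 0.5 Å
for high accuracy): a node is accessible for dye radius R if no atom
inflated by R overlaps it and the shortest path from the attachment atom
through space free for the width-w linker tube is at most the linker length
L.  Path lengths are Dijkstra distances over the primitive-offset
neighbourhood of radius 3 (collinear offsets removed, long edges checked for
occlusion of intermediate cells); this keeps the grid metric within ~2.5% of
Euclidean, where a plain 26-neighbour graph overestimates by up to ~8% and
shrinks free-space volumes by >20%.  The three-radii AV superposes the
clouds of three dye radii with equal weight.  Dye/linker geometries shipped
in `DYE_PARAMS` are representative values for C6-amino-linker NHS-ester
labelling, not fitted constants, and reproduction of published AV distance
columns is a validation exercise requiring the real structures and dye
parameters — deliberately out of scope for the automated checks.

FRET-averaged distances: E_avg = ⟨1/(1+(r/R₀)⁶)⟩ over weighted point pairs
(exhaustive when small, seeded Monte-Carlo above `n_pairs`), then
⟨R_DA⟩_E = R₀·((1−E_avg)/E_avg)^(1/6).  The rotation scan rigidly rotates a
selected half of the assembly about a user-chosen axis (a heuristic helper
proposes the line through the half-centroids) in steps dividing 360°,
recomputing both AVs and ⟨R_DA⟩_E at each angle; the profile equals the
unrotated geometry at 0° and closes at 360° to within grid tolerance.

## Reproducibility and problem sizes

A pipeline run is fully determined by its configuration and master seed;
stage seeds derive as `SeedSequence((master_seed, stage_index))` with
recorded indices, so stages can be re-run in isolation.  The default test
suite runs its stochastic end-to-end checks at 80–120 traces per dataset and
the acceptance script at the study scale of 10 replicates × 200 traces ×
25 s (50 ms frames), with TDP clustering at K = 1..10 × 30 initializations
and 100 bootstrap samples throughout; these sizes are the package's standard
operating points and complete in minutes on one CPU.

## Known limitations

* The state-lifetimes estimator inherits the biases of its inputs: Viterbi
  decoding under-reports one-frame dwells and fast intermediate transitions
  appear as skipped states, so non-adjacent transition classes carry weight
  that the linear chain does not generate directly.
* The BIC margin between K = 4 and K = 5 can be small (tens of points on
  ~10⁴) when a handful of traces still contribute off-grid levels; an
  occasional extra state at a preset's blur band is possible and downstream
  consumers should select states by level, not index.
* The printed Δk_av recipe is dimensionally a time; it is reproduced as
  printed and the corrected mode is opt-in.
* AV clouds ignore dye-specific photophysics (κ² distributions, quenching);
  distances are ideal-Förster averages over geometry only.
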