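# Methods

## The cycle model

The package models the canonical hand-over-hand kinesin cycle as a linear
sequence of first-order transitions with one branch point. Numbering the
microtubule-bound states 3–7: the bound head waits for ATP (3), binds ATP
(4), hydrolyses it (5); from the weakly bound post-hydrolysis state 5 the
tethered head either attaches to the next tubulin site (rate `kon_th`,
→ 6) or the bound head detaches and the run ends (rate `k_detach_weak`);
ADP release by the new front head (6 → 7) completes the 8-nm step, and
rear-head detachment (7 → 3) resets the cycle. Landing kinetics (solution
states 1–2) enter only through the second-order microtubule on-rate used in
stopped-flow emulation; the simulator starts runs in state 3, matching how
motility assays score events.

Assumptions inherited by everything downstream:

- all transitions are memoryless (exponential waiting times), so runs are
  geometric in step count and exponential in length;
- the reverse of tethered-head attachment (6 → 5) is off by default
  (`k_off_th = 0`): no reverse rate has been measured;
- detachment from the weak state uses the ADP-state off-rate as a proxy for
  the ADP-Pᵢ state; the model keeps a single `k_detach_weak` and does not
  resolve whether Pᵢ release precedes dissociation;
- no load dependence, no backstepping, no futile hydrolysis, no pause
  states. Kymograph pauses are real but unexplained by this cycle, which is
  why two velocities exist in the inputs (1.56 μm/s with pauses, 1.77 μm/s
  without); the simulator reproduces pause-free kinetics only.

Rates that are experimentally unresolvable are represented by a `FAST`
sentinel (`math.inf`). A FAST transition contributes zero duration to time
budgets and consumes no random numbers in simulation. This applies to the
hydrolysis rate — the most poorly defined constant in the cycle, left
configurable — and to rear-head detachment, whose half-site/stepping-rate
difference is non-positive for KIF1A (the algebra returns FAST rather than
a negative rate).

### Default rate set (units: s⁻¹, μM⁻¹s⁻¹, nm)

`RateSet()` carries the measured KIF1A constants: `kon_mt = 17`,
`kon_atp = 1.4` (a lower bound: the half-site maximal rate divided by its
half-saturating ATP concentration), `k_hyd = FAST`, `kon_th = 189` (kinetic
race inverted at 700 steps per run), `koff_adp_fh = 354` (unstrained mADP
off-rate; the strained rate is faster but unmeasurable), `koff_rh = FAST`,
`k_detach_weak = 0.27` (microtubule off-rate in saturating ADP),
`koff_apo = 0.09`, `step_size = 8`. At 2 mM ATP these give an 8.47-ms cycle
(118 s⁻¹) — slower than the 220 s⁻¹ stepping rate measured directly, a
known tension in the input data that the package reports but does not
reconcile.

Both forms of the kinetic race are exposed. The approximate inversion
`kon_th = k_detach·n_steps` is the default because it reproduces the
reported constants; the exact form `k_detach·(n_steps − 1)` differs by
0.14% at 700 steps.

## Run-length inference

The censored-exponential MLE is the package's statistical core. Its
derivation treats the distance-to-end `t` as a known covariate; because a
censored run is recorded at the track end (`y = t` when `w = 0`), the
general estimator `θ̂ = (Σ wy + Σ (1−w)t)/Σ w` reduces to `Σ y / Σ w`, and
only `(y, w)` pairs are required. The variance is the inverse Fisher
information `θ²/Σ(1 − e^{−tᵢ/θ})`, evaluated by plug-in at `θ̂` since θ is
unknown. Numerical notes:

- the estimator is undefined when every run is censored (`Σw = 0`); this
  raises rather than returning infinity;
- an optional detection cutoff drops events with `y ≤ cutoff` and subtracts
  the cutoff from the remainder, relying on memorylessness; for censored
  events this is an approximation (their `t` is shifted too);
- the bootstrap resamples `(y, w, t)` triples intact and redraws (with a
  warning) the rare all-censored resample; percentile intervals are used,
  not BCa, with 10⁴ replicates by default;
- the Kaplan–Meier comparison uses lifelines' product-limit estimator with
  the restricted mean taken at the largest observation. It is the
  independent cross-check, expected to sit within ~10% of the MLE at
  moderate (<40%) censoring and to undershoot when censoring is heavy in
  the tail;
- the truncated-CDF fit (`1 − exp(−(x − cutoff)/θ)` least-squares against
  the empirical CDF of values above the cutoff) estimates the
  *uncorrected* mean run length; the empirical CDF is used directly (no
  binning, Hazen plotting positions). It exists to reproduce the naive
  estimate, not to replace the MLE.

## Simulation

Runs are simulated with the Gillespie direct method: one exponential
waiting time per composite transition and one uniform draw to resolve the
state-5 race. Two code paths share the same model: a scalar event-logging
path for single trajectories, and a chunk-vectorized path for ensembles
(identical distributions; the two paths consume random numbers in a
different order, so they are not trajectory-identical at the same seed —
each path is individually deterministic under its seed). Ensembles use one
master seed with per-run child streams, so results do not depend on
chunking or run order.

Position advances one full step at ADP release (6 → 7); sub-step head
positions are not modelled. On a finite track, a run is censored when the
next step would pass the plus end; the check happens on attachment (the
race in state 5 still resolves first, so a detachment at the last site
counts as a detachment). Censored runs record `y = t` exactly, matching the
estimator's convention; end pausing is not modelled. Runs that reach
`max_steps` are tagged `capped` and excluded from run tables with a
warning.

## Kinetics fitting

All fitters initialise deterministically so repeated fits are identical:
exponentials from a log-linear regression of the baseline-subtracted
signal, hyperbolae from the data extrema and the median concentration.
Stopped-flow fits start at the 2-ms instrument dead time by default
(configurable); restricting an exponential to `t ≥ t₀` leaves its rate
unbiased, so the dead time costs amplitude information only. Two-phase fits
are built sequentially: the single-phase solution seeds the fast phase and
a small slow phase is added, so genuinely single-phase data keeps a
negligible second amplitude instead of splitting one rate across two
phases. The fast phase is reported as `k_obs` (the convention for
microtubule-binding transients, where the slow phase is release from the
second head).

Saturation fits use `rate = baseline + (kmax − baseline)·c/(K + c)` with
the baseline fixed at zero except for the off-rate-vs-[ADP] form, where the
baseline is the apo-state off-rate. Weights follow the 1/SEM convention;
absent or zero SEMs mean equal weights, which reproduces the unweighted
fit exactly. A fitted `K` outside the sampled concentration range is
flagged as an extrapolation. The three-parameter off-rate curve is
intrinsically ill-conditioned with few concentrations — with the four
measured [ADP] points its K_D confidence interval spans hundreds of μM —
so tests assert convergence and interval-width behaviour rather than a
point value.

Dwell-time distributions are fit as `F(t) = 1 − exp(−(t − t₀)/τ)` against
the empirical CDF at the unique observed values, with the location `t₀`
free. The offset absorbs the camera detection limit: dwells quantized to
whole frames with a minimum detectable length form an exponential on a
shifted grid, and the free-offset fit recovers the true τ where a
zero-offset fit would be biased by the missing short events. The off-rate
is 1/τ.

All fitting APIs take final chamber concentrations; the stopped-flow
convention that syringe concentrations are twice the chamber values is a
bookkeeping matter for the experimentalist, not the fitter.

## Synthetic data

The generators define the study conditions used throughout the tests:

- **Run tables** — exponential run lengths (default θ = 5.6 μm, n = 534),
  tracks uniform on 8–20 μm (no track-length distribution was reported;
  this range yields the observed ~36% censored fraction and is
  configurable), landing positions uniform along the track.
- **Traces** — sums of exponentials plus i.i.d. Gaussian noise (default sd
  2% of total amplitude), 2-ms dead time, samples before the dead time
  retained but flagged. Averaging replicate shots reduces noise by √n as
  for a real instrument; photobleaching and drift are not modelled.
- **Dwell tables** — exponential dwells rounded *up* to whole frames
  (default 0.2 s, i.e. 5 fps) with events under 2 frames dropped — a
  common detection limit, configurable, not a reported value.
- **k_obs series** — linear (`29c + 354` for nucleotide exchange, `17c`
  for microtubule binding) or hyperbolic (`172/119` half-site, `115/1.2`
  ATPase) concentration dependences with optional Gaussian noise recorded
  in the SEM column.

Because the generators share the cycle model's assumptions, passing tests
demonstrate internal consistency of the estimators under exponential/
Gaussian statistics — they cannot certify behaviour on real data with
pauses, photobleaching, non-exponential dwells or correlated noise.

## Problem sizes and tolerances

Ensemble checks use 5 000–10 000 runs (Monte-Carlo SE on the 5.6-μm mean
run length at n = 5000 is ~0.08 μm); estimator-consistency and CI-coverage
checks use 500–1000 replicates of n = 534 events, the size of the measured
data set. Goodness-of-fit assertions are evaluated at α = 0.01 on two
independent seeded ensembles, requiring one pass — a correct model fails
both with probability ~10⁻⁴, so the test stays sharp without being a 1%
coin flip. Closed-form estimators are checked against independent numeric
optimisation at 10⁻⁸ relative tolerance; noiseless fitter recoveries at
10⁻⁴ or better.

## Known limitations

- The cycle-time budget built from the measured constants (8.5 ms) exceeds
  the measured step duration (4.5 ms); the inputs are mutually
  inconsistent at that level and the package surfaces both numbers.
- The weak-state detachment proxy (ADP off-rate) and the unstrained ADP
  release rate both stand in for strained quantities that cannot be
  measured; simulated velocities are correspondingly lower than measured.
- The censored-run correction assumes exponential run lengths; it is not
  valid for motors with non-exponential (e.g. gamma) run-length
  distributions, and photobleaching-limited observation is not treated.
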