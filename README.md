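# motorcycle

Kinetics of processive kinesin chemomechanical cycles — built around the
fast, superprocessive kinesin-3 motor KIF1A.

Dimeric kinesins walk hand-over-hand along microtubules, advancing 8 nm per
ATP hydrolysed, until they dissociate. Two questions organise the analysis
this package supports:

1. **How long does one step take, and which transition is rate-limiting?**
   The cycle time at ATP concentration `[T]` decomposes into the sequential
   transition durations

   ```
   1/k_cycle = 1/(kon_ATP·[T]) + 1/k_hyd + 1/kon_TH + 1/koff_ADP + 1/koff_RH
   ```

   (ATP binding, hydrolysis, tethered-head attachment, front-head ADP
   release, rear-head detachment). Transitions too fast to measure carry a
   `FAST` sentinel and contribute zero duration.

2. **Why does the motor stay on for hundreds of steps?** Processivity is a
   kinetic race out of the weakly bound post-hydrolysis state: the tethered
   head attaches at rate `kon_TH`, or the bound head detaches at rate
   `k_detach`. The per-step detachment probability is

   ```
   p_detach = k_detach / (kon_TH + k_detach) ≈ k_detach / kon_TH
   ```

   so the mean run is `1/p_detach` steps. Measuring the run length and the
   weak-state off-rate pins down `kon_TH`.

Measured run lengths are biased low because motors run off the ends of
finite microtubules. With observed length `y = min(x, t)` (`t` = distance
from the landing point to the track end) and detachment indicator `w`, the
censored-exponential maximum-likelihood estimate of the mean run length is

```
θ̂ = Σ yᵢ / Σ wᵢ  =  naive mean / fraction detached,
Var(θ̂) = θ̂² / Σ (1 − exp(−yᵢ/θ̂))        (Fisher information)
```

— if half the runs are censored, the naive mean is corrected up by exactly
a factor of two.

The package provides:

- `cycle` / `rates` — the deterministic algebra above (race, inversion,
  time budgets, off-rate-vs-[ADP] hyperbola, unit conversions);
- `simulate` — a Gillespie simulator of the stepping cycle on finite
  microtubules, emitting trajectories and censored run tables;
- `runlength` — the censored-exponential MLE with asymptotic and bootstrap
  uncertainty, a Kaplan–Meier cross-check (via lifelines), and the
  truncated-CDF fit used for uncorrected run lengths;
- `kinetics` — scikit-learn-style fitters for stopped-flow transients
  (1–2 exponentials with a 2-ms instrument dead time), linear
  k_obs-vs-concentration, weighted saturation (Michaelis–Menten)
  curves, dwell-time distributions, and half-site amplitude ratios;
- `synth` — seeded generators emulating each assay's statistical structure;
- a `motorcycle` CLI over all of the above.

## Worked example

Simulate 5000 runs of the measured KIF1A cycle on 12-μm microtubules at
saturating ATP, then correct the run length for end-of-track censoring:

```python
from motorcycle import (RateSet, TrackGeometry, simulate_ensemble,
                        censored_mle, cycle_time_budget)

rates = RateSet()                      # measured KIF1A rate set
runs = simulate_ensemble(rates, atp_conc_um=2000, n_runs=5000,
                         geometry=TrackGeometry(length_um=12.0), seed=7)
print(runs["censored"].mean())         # 0.41 — 41% ran off the track end
est = censored_mle(runs)
print(est.naive_mean, est.theta_hat, est.se)
# 3.34  5.65  0.10   (μm)
print(cycle_time_budget(rates, 2000).as_text_table())
```

```
transition                       duration (ms)  occupancy (%)
atp_binding                             0.3571           4.22
hydrolysis (fast)                            0           0.00
tethered_head_attachment                 5.291          62.45
front_head_adp_release                   2.825          33.34
rear_head_detachment (fast)                  0           0.00
total                                    8.473         100.00
cycle rate: 118 s^-1
```

The naive mean run length (3.34 μm) understates the true 5.6-μm
processivity because 41% of runs were cut short by the track end; the
censored MLE recovers 5.65 ± 0.10 μm. The time budget shows the motor
spends ~62% of its cycle waiting for tethered-head attachment — the
rate-limiting transition — and essentially no time in the two-heads-bound
states.

The same analyses are available from the shell, e.g.:

```
motorcycle simulate-runs --atp 2000 --n 5000 --mt-length 12 --seed 7 -o runs.csv
motorcycle fit-runlength runs.csv --bootstrap 10000 --seed 7
motorcycle table1
```

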