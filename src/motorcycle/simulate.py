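"""Stochastic (Gillespie) simulation of the kinesin stepping cycle.

The simulated cycle follows the canonical hand-over-hand scheme. A run
starts in the one-head-bound ATP-waiting state (state 3, one ADP already
released). Each attempted step then proceeds:

* state 3 → 4: ATP binding, pseudo-first-order rate ``kon_atp·[ATP]``
* state 4 → 5: hydrolysis, rate ``k_hyd``
* state 5: kinetic race — tethered-head attachment ``kon_th`` (→ state 6)
  versus detachment of the bound head ``k_detach_weak`` (run terminates)
* state 6 → 7: front-head ADP release at ``koff_adp_fh``; the motor
  position advances one ``step_size`` here (ADP release completes the step)
* state 7 → 3: rear-head detachment at ``koff_rh``

FAST transitions are instantaneous and consume no random numbers. On a
finite track the run is censored (``ran_off_end``) when the next step would
carry the motor past the plus end; end pausing is not modelled. Pauses seen
in kymographs are likewise not modelled — the simulator reproduces
pause-free kinetics.

Run tables use the CSV convention ``censored = 1`` for runs that reached
the track end; the inference module's detachment indicator is ``w = 1 -
censored``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .rates import RateSet, is_fast

__all__ = [
    "TrackGeometry",
    "Trajectory",
    "simulate_run",
    "simulate_ensemble",
    "summarize_ensemble",
    "RUN_TABLE_COLUMNS",
]

RUN_TABLE_COLUMNS = (
    "run_length_um",
    "censored",
    "dist_to_end_um",
    "mt_length_um",
    "run_time_s",
    "n_steps",
)

_CHUNK = 1024


@dataclass(frozen=True)
class TrackGeometry:
    """Microtubule geometry for one run.

    ``length_um`` may be ``inf`` for an effectively unbounded track.
    ``landing_um`` is the landing position measured from the minus end;
    ``None`` means "sample uniformly along the track". The motor walks
    toward the plus end, so the distance available before censoring is
    ``length_um - landing_um``.
    """

    length_um: float = math.inf
    landing_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("track length must be > 0")
        if self.landing_um is not None:
            if not 0 <= self.landing_um <= self.length_um:
                raise ValueError("landing position must lie on the track")

    def sample_dist_to_end_um(self, rng: np.random.Generator) -> float:
        if math.isinf(self.length_um):
            return math.inf
        landing = (
            rng.uniform(0.0, self.length_um)
            if self.landing_um is None
            else self.landing_um
        )
        return self.length_um - landing


@dataclass
class Trajectory:
    """One simulated run: event log plus summary quantities."""

    #: (state id, entry time s, position nm) triples; states per the cycle
    #: scheme (3 ATP-wait, 4 post-binding, 5 post-hydrolysis weak state,
    #: 6 two-heads-bound pre-ADP-release, 7 two-heads-bound tight).
    events: Optional[List[Tuple[int, float, float]]]
    termination: str  # 'detached' | 'ran_off_end' | 'capped'
    total_time_s: float
    n_steps: int
    run_length_um: float
    dist_to_end_um: float
    mt_length_um: float


def _validate_cycle_rates(rates: RateSet, atp_conc_um: float) -> None:
    if atp_conc_um <= 0:
        raise ValueError("ATP concentration must be > 0")
    if is_fast(rates.kon_atp):
        raise ValueError("kon_atp must be finite")
    race_total = rates.kon_th + rates.k_detach_weak
    if race_total == 0:
        raise ValueError(
            "absorbing state: no exit from the post-hydrolysis state "
            "(kon_th and k_detach_weak both zero)"
        )
    for name, rate in (
        ("kon_atp*[ATP]", rates.kon_atp * atp_conc_um),
        ("k_hyd", rates.k_hyd),
        ("koff_adp_fh", rates.koff_adp_fh),
        ("koff_rh", rates.koff_rh),
    ):
        if rate == 0:
            raise ValueError(f"absorbing state: transition {name!r} has zero rate")


def _exp_or_zero(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    """Exponential waiting times for a finite rate; zeros for FAST."""
    if is_fast(rate):
        return np.zeros(size)
    return rng.exponential(1.0 / rate, size)


def _simulate_fast(
    rates: RateSet,
    atp_conc_um: float,
    dist_to_end_um: float,
    max_steps: int,
    rng: np.random.Generator,
) -> Tuple[int, float, str]:
    """Chunk-vectorized run without event logging.

    Returns (completed steps, total time s, termination).
    """
    step_nm = rates.step_size
    r_atp = rates.kon_atp * atp_conc_um
    race_total = rates.kon_th + rates.k_detach_weak
    if is_fast(rates.k_detach_weak):
        p_detach = 1.0
    elif is_fast(rates.kon_th):
        p_detach = 0.0
    else:
        p_detach = rates.k_detach_weak / race_total

    # Maximum number of completed steps the track allows: the attempt with
    # 0-based index n_track (if reached) steps past the plus end.
    if math.isinf(dist_to_end_um):
        n_track: Optional[int] = None
    else:
        n_track = int(math.floor(dist_to_end_um * 1e3 / step_nm))

    steps = 0
    t = 0.0
    while steps < max_steps:
        m = min(_CHUNK, max_steps - steps)
        if n_track is not None:
            # allow the chunk to include the attempt that would run off
            m = min(m, n_track - steps + 1)
        pre = _exp_or_zero(rng, r_atp, m)
        pre += _exp_or_zero(rng, rates.k_hyd, m)
        pre += _exp_or_zero(rng, race_total, m)
        u = rng.random(m)
        post = _exp_or_zero(rng, rates.koff_adp_fh, m)
        post += _exp_or_zero(rng, rates.koff_rh, m)

        detach_hits = np.nonzero(u < p_detach)[0]
        i_detach = int(detach_hits[0]) if detach_hits.size else m
        i_off = (n_track - steps) if n_track is not None else m

        if i_detach <= i_off and i_detach < m:
            # detachment in state 5 of attempt i_detach (before any check
            # against the track end, which only applies on attachment)
            t += float(pre[: i_detach + 1].sum() + post[:i_detach].sum())
            return steps + i_detach, t, "detached"
        if i_off < i_detach and i_off < m:
            # tethered head attached but the step would pass the plus end
            t += float(pre[: i_off + 1].sum() + post[:i_off].sum())
            return steps + i_off, t, "ran_off_end"
        t += float(pre.sum() + post.sum())
        steps += m
    return steps, t, "capped"


def _simulate_logged(
    rates: RateSet,
    atp_conc_um: float,
    dist_to_end_um: float,
    max_steps: int,
    rng: np.random.Generator,
) -> Tuple[int, float, str, List[Tuple[int, float, float]]]:
    """Scalar event-logging run (reference path)."""
    step_nm = rates.step_size
    r_atp = rates.kon_atp * atp_conc_um
    race_total = rates.kon_th + rates.k_detach_weak
    p_detach = (
        1.0
        if is_fast(rates.k_detach_weak)
        else (0.0 if is_fast(rates.kon_th) else rates.k_detach_weak / race_total)
    )
    end_nm = dist_to_end_um * 1e3

    def dwell(rate: float) -> float:
        return 0.0 if is_fast(rate) else rng.exponential(1.0 / rate)

    events: List[Tuple[int, float, float]] = []
    t = 0.0
    pos_nm = 0.0
    steps = 0
    while steps < max_steps:
        events.append((3, t, pos_nm))
        t += dwell(r_atp)
        events.append((4, t, pos_nm))
        t += dwell(rates.k_hyd)
        events.append((5, t, pos_nm))
        t += dwell(race_total)
        if rng.random() < p_detach:
            return steps, t, "detached", events
        if pos_nm + step_nm > end_nm:
            return steps, t, "ran_off_end", events
        events.append((6, t, pos_nm))
        t += dwell(rates.koff_adp_fh)
        pos_nm += step_nm
        events.append((7, t, pos_nm))
        t += dwell(rates.koff_rh)
        steps += 1
    return steps, t, "capped", events


def simulate_run(
    rates: RateSet,
    atp_conc_um: float,
    geometry: Optional[TrackGeometry] = None,
    seed: Union[int, np.random.Generator, np.random.SeedSequence, None] = None,
    max_steps: int = 1_000_000,
    record_events: bool = True,
) -> Trajectory:
    """Simulate one processive run; identical seeds give identical runs."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    _validate_cycle_rates(rates, atp_conc_um)
    geometry = geometry or TrackGeometry()
    rng = np.random.default_rng(seed)
    dist_to_end = geometry.sample_dist_to_end_um(rng)

    if record_events:
        steps, t, term, events = _simulate_logged(
            rates, atp_conc_um, dist_to_end, max_steps, rng
        )
    else:
        steps, t, term = _simulate_fast(
            rates, atp_conc_um, dist_to_end, max_steps, rng
        )
        events = None

    if term == "ran_off_end":
        run_length_um = dist_to_end  # the motor reached the track end
    else:
        run_length_um = steps * rates.step_size * 1e-3
    return Trajectory(
        events=events,
        termination=term,
        total_time_s=t,
        n_steps=steps,
        run_length_um=run_length_um,
        dist_to_end_um=dist_to_end,
        mt_length_um=geometry.length_um,
    )


def simulate_ensemble(
    rates: RateSet,
    atp_conc_um: float,
    n_runs: int,
    geometry: Optional[TrackGeometry] = None,
    seed: Union[int, np.random.SeedSequence, None] = None,
    max_steps: int = 1_000_000,
) -> pd.DataFrame:
    """Simulate *n_runs* independent runs and collect a run table.

    One master seed; each run gets its own deterministic child stream, so
    the table is reproducible and independent of chunking. Runs that hit
    ``max_steps`` (``capped``) are excluded from the table with a warning.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    _validate_cycle_rates(rates, atp_conc_um)
    geometry = geometry or TrackGeometry()
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = master.spawn(n_runs)

    rows = []
    n_capped = 0
    for child in children:
        rng = np.random.default_rng(child)
        dist_to_end = geometry.sample_dist_to_end_um(rng)
        steps, t, term = _simulate_fast(
            rates, atp_conc_um, dist_to_end, max_steps, rng
        )
        if term == "capped":
            n_capped += 1
            continue
        censored = 1 if term == "ran_off_end" else 0
        y = dist_to_end if censored else steps * rates.step_size * 1e-3
        rows.append((y, censored, dist_to_end, geometry.length_um, t, steps))
    if n_capped:
        warnings.warn(
            f"{n_capped} run(s) hit max_steps={max_steps} and were excluded",
            stacklevel=2,
        )
    if not rows:
        raise RuntimeError("all runs were capped; increase max_steps")
    return pd.DataFrame(rows, columns=list(RUN_TABLE_COLUMNS))


def summarize_ensemble(runs: pd.DataFrame) -> dict:
    """Ensemble motility summary from a run table.

    Velocity is total displacement over total bound time. The mean run
    length is computed from detached (uncensored) runs only — the naive
    observable; use the censored-MLE estimator for the corrected value.
    """
    if len(runs) == 0:
        raise ValueError("empty run table")
    detached = runs[runs["censored"] == 0]
    out = {
        "n_runs": int(len(runs)),
        "n_censored": int(runs["censored"].sum()),
        "mean_velocity_um_s": float(
            runs["run_length_um"].sum() / runs["run_time_s"].sum()
        ),
        "mean_run_time_s": float(runs["run_time_s"].mean()),
        "mean_run_length_um": float(
            detached["run_length_um"].mean() if len(detached) else math.nan
        ),
        "mean_steps": float(runs["n_steps"].mean()),
    }
    return out
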