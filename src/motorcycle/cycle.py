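"""Deterministic algebra of the kinesin chemomechanical cycle.

Processivity of a stepping kinesin is set by a kinetic race out of the
weakly bound post-hydrolysis state: the tethered head attaches to the next
tubulin site at rate ``kon_th`` (the run continues) or the bound head
detaches from the microtubule at rate ``k_detach_weak`` (the run ends).
Because the two clocks are exponential, the per-step detachment probability
is

    p_detach = k_detach_weak / (kon_th + k_detach_weak)
             ≈ k_detach_weak / kon_th        (kon_th >> k_detach_weak)

and the mean number of steps per run is 1/p_detach. The total cycle time at
a given ATP concentration decomposes into the sum of the mean durations of
the sequential transitions (ATP binding, hydrolysis, tethered-head
attachment, front-head ADP release, rear-head detachment); transitions too
fast to measure (FAST) contribute zero duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

from .rates import FAST, RateSet, is_fast

__all__ = [
    "OffRateCurveParams",
    "CycleBudget",
    "p_detach_per_step",
    "kon_th_from_processivity",
    "cycle_time_budget",
    "rear_head_rate_from_half_site",
    "off_rate_at_adp",
    "atp_on_rate_lower_bound",
    "derived_motility_quantities",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round *x* to *sig* significant figures (reporting convention).

    Internal computation is always full precision; this helper exists only
    for report output, where kinetic constants are conventionally quoted to
    two significant figures.
    """
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class OffRateCurveParams:
    """Parameters of the microtubule off-rate vs [ADP] hyperbola.

    koff(ADP) rises from the apo-state off-rate ``koff_apo`` to the
    saturating-nucleotide off-rate ``koff_max`` with half-saturation at
    ``k_d`` (μM), the effective K_D of the motor–microtubule complex for
    ADP.
    """

    koff_apo: float
    koff_max: float
    k_d: float
    #: True when koff_max < koff_apo (curve not monotonically increasing).
    non_monotonic: bool = field(init=False)

    def __post_init__(self) -> None:
        for name in ("koff_apo", "koff_max", "k_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "non_monotonic", self.koff_max < self.koff_apo)


@dataclass(frozen=True)
class CycleBudget:
    """Per-transition time budget of one stepping cycle.

    Durations are in ms; ``occupancy_percent`` gives each transition's share
    of the total cycle time. FAST transitions have zero duration and are
    listed in ``fast_transitions``.
    """

    durations_ms: Dict[str, float]
    total_ms: float
    occupancy_percent: Dict[str, float]
    fast_transitions: tuple
    cycle_rate_per_s: float

    def as_dict(self) -> dict:
        return {
            "durations_ms": dict(self.durations_ms),
            "total_ms": self.total_ms,
            "occupancy_percent": dict(self.occupancy_percent),
            "fast_transitions": list(self.fast_transitions),
            "cycle_rate_per_s": self.cycle_rate_per_s,
        }

    def as_text_table(self) -> str:
        lines = [f"{'transition':<32}{'duration (ms)':>14}{'occupancy (%)':>15}"]
        for name, dur in self.durations_ms.items():
            tag = " (fast)" if name in self.fast_transitions else ""
            lines.append(
                f"{name + tag:<32}{dur:>14.4g}{self.occupancy_percent[name]:>15.2f}"
            )
        lines.append(f"{'total':<32}{self.total_ms:>14.4g}{100.0:>15.2f}")
        lines.append(f"cycle rate: {self.cycle_rate_per_s:.4g} s^-1")
        return "\n".join(lines)


def p_detach_per_step(
    k_detach_weak: float, kon_th: float, *, approximate: bool = False
) -> float:
    """Per-step detachment probability from the weak-state kinetic race.

    Exact form: k_detach_weak / (kon_th + k_detach_weak). With
    ``approximate=True`` returns the high-processivity approximation
    k_detach_weak / kon_th, valid for kon_th >> k_detach_weak.
    """
    if k_detach_weak < 0 or kon_th < 0:
        raise ValueError("rates must be >= 0")
    if k_detach_weak == 0 and kon_th == 0:
        raise ValueError("undefined race: both competing rates are zero")
    if approximate:
        if kon_th == 0:
            raise ValueError("approximate form requires kon_th > 0")
        return k_detach_weak / kon_th
    if is_fast(kon_th):
        return 0.0
    if is_fast(k_detach_weak):
        return 1.0
    return k_detach_weak / (kon_th + k_detach_weak)


def kon_th_from_processivity(
    k_detach_weak: float, n_steps: float, *, exact: bool = False
) -> float:
    """Tethered-head attachment rate implied by a mean run of *n_steps*.

    Inverts the kinetic race: with p_detach = 1/n_steps, the rearrangement
    kon_th = k_detach_weak / p_detach = k_detach_weak * n_steps
    (high-processivity form, the default). ``exact=True`` uses the exact
    inversion kon_th = k_detach_weak * (n_steps - 1).
    """
    if k_detach_weak <= 0:
        raise ValueError("k_detach_weak must be > 0")
    if n_steps < 1:
        raise ValueError("mean steps per run must be >= 1")
    if exact:
        return k_detach_weak * (n_steps - 1.0)
    return k_detach_weak * n_steps


def _duration_s(rate: float, label: str) -> float:
    """Mean duration of a first-order transition; FAST counts as zero."""
    if is_fast(rate):
        return 0.0
    if rate <= 0:
        raise ValueError(
            f"transition {label!r} has zero rate: infinite duration"
        )
    return 1.0 / rate


def cycle_time_budget(rates: RateSet, atp_conc_um: float) -> CycleBudget:
    """Decompose the cycle time into per-transition durations at given [ATP].

    1/k_cycle = 1/(kon_atp·[ATP]) + 1/k_hyd + 1/kon_th + 1/koff_adp_fh
                + 1/koff_rh, with FAST transitions contributing 0.
    """
    if atp_conc_um <= 0:
        raise ValueError("ATP concentration must be > 0")
    if is_fast(rates.kon_atp):
        raise ValueError("kon_atp must be finite")
    pseudo_first_order = {
        "atp_binding": rates.kon_atp * atp_conc_um,
        "hydrolysis": rates.k_hyd,
        "tethered_head_attachment": rates.kon_th,
        "front_head_adp_release": rates.koff_adp_fh,
        "rear_head_detachment": rates.koff_rh,
    }
    durations_ms = {
        name: 1e3 * _duration_s(rate, name)
        for name, rate in pseudo_first_order.items()
    }
    fast = tuple(n for n, r in pseudo_first_order.items() if is_fast(r))
    total_ms = sum(durations_ms.values())
    if total_ms <= 0:
        raise ValueError("all transitions FAST: cycle time is zero")
    occupancy = {n: 100.0 * d / total_ms for n, d in durations_ms.items()}
    return CycleBudget(
        durations_ms=durations_ms,
        total_ms=total_ms,
        occupancy_percent=occupancy,
        fast_transitions=fast,
        cycle_rate_per_s=1e3 / total_ms,
    )


def rear_head_rate_from_half_site(k_step: float, k_max_hs: float) -> float:
    """Rear-head detachment rate from stepping vs half-site release rates.

    The half-site release measurement covers every transition in the cycle
    except rear-head detachment, so the missing duration is
    1/koff_rh = 1/k_step − 1/k_max_hs. When the half-site rate does not
    exceed the stepping rate the difference is non-positive and the rate is
    unresolvable: the FAST sentinel is returned.
    """
    if k_step <= 0 or k_max_hs <= 0:
        raise ValueError("rates must be > 0")
    if k_max_hs <= k_step:
        return FAST
    return 1.0 / (1.0 / k_step - 1.0 / k_max_hs)


def off_rate_at_adp(params: OffRateCurveParams, adp_conc_um: float) -> float:
    """Microtubule off-rate at a given [ADP] from the saturation hyperbola.

    koff([ADP]) = koff_apo + (koff_max − koff_apo)·[ADP]/(K_D + [ADP]).
    """
    if adp_conc_um < 0:
        raise ValueError("ADP concentration must be >= 0")
    if math.isinf(adp_conc_um):
        return params.koff_max
    return params.koff_apo + (params.koff_max - params.koff_apo) * adp_conc_um / (
        params.k_d + adp_conc_um
    )


def atp_on_rate_lower_bound(k_max: float, k_half_um: float) -> float:
    """Lower bound on the second-order ATP on-rate, k_max / K_0.5 (μM⁻¹s⁻¹).

    At the half-saturating nucleotide concentration the binding step takes
    half the total time, so binding proceeds at k_max there; dividing by
    K_0.5 gives the implied second-order rate. Reversible binding would
    require an even faster on-rate, hence "lower bound".
    """
    if k_max <= 0 or k_half_um <= 0:
        raise ValueError("inputs must be > 0")
    return k_max / k_half_um


def derived_motility_quantities(
    velocity_um_s: float,
    run_length_um: float,
    step_size_nm: float = 8.0,
    *,
    sig_figs: Optional[int] = None,
) -> Dict[str, float]:
    """Derived single-molecule quantities from velocity and run length.

    Returns stepping rate (velocity/step), mean steps per run
    (run length/step), microtubule off-rate (velocity/run length), mean run
    time (run length/velocity) and mean step duration. Pass ``sig_figs=2``
    for report-style rounding; default is full precision.
    """
    if velocity_um_s <= 0 or step_size_nm <= 0:
        raise ValueError("velocity and step size must be > 0")
    if run_length_um <= 0:
        raise ZeroDivisionError("run length must be > 0")
    step_um = step_size_nm * 1e-3
    out = {
        "stepping_rate_per_s": velocity_um_s / step_um,
        "n_steps": run_length_um / step_um,
        "koff_mt_per_s": velocity_um_s / run_length_um,
        "run_time_s": run_length_um / velocity_um_s,
        "step_duration_ms": 1e3 * step_um / velocity_um_s,
    }
    if sig_figs is not None:
        out = {k: round_sig(v, sig_figs) for k, v in out.items()}
    return out
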