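"""Rate-constant containers for the kinesin chemomechanical cycle.

A processive kinesin dimer completes one 8-nm step per ATP hydrolysed. The
transitions of the canonical cycle are parameterised here by first- and
second-order rate constants. Transitions that are experimentally too fast to
resolve are represented by the ``FAST`` sentinel (``math.inf``): they
contribute zero duration to any time budget and are reported as "Fast".
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

#: Sentinel for a transition too fast to measure (contributes zero duration).
FAST: float = math.inf

#: Canonical step size of a dimeric kinesin, nm per completed cycle.
STEP_SIZE_NM: float = 8.0


def is_fast(rate: float) -> bool:
    """True if *rate* is the FAST (unmeasurably large) sentinel."""
    return math.isinf(rate) and rate > 0


def _parse_rate(value: Union[float, int, str]) -> float:
    if isinstance(value, str):
        if value.strip().lower() == "fast":
            return FAST
        return float(value)
    return float(value)


def _format_rate(value: float) -> Union[float, str]:
    return "fast" if is_fast(value) else value


@dataclass
class RateSet:
    """Named rate constants of the stepping cycle.

    Parameters
    ----------
    kon_mt : float
        Second-order microtubule on-rate from solution (μM⁻¹ s⁻¹).
    kon_atp : float
        Second-order ATP on-rate of the bound head (μM⁻¹ s⁻¹).
    k_hyd : float
        ATP hydrolysis rate (s⁻¹); may be ``FAST``.
    kon_th : float
        Tethered-head attachment rate to the next tubulin site (s⁻¹).
    koff_adp_fh : float
        ADP release rate by the newly bound front head (s⁻¹).
    koff_rh : float
        Rear-head detachment rate completing the step (s⁻¹); may be ``FAST``.
    k_detach_weak : float
        Detachment rate of the bound head from the weakly bound
        post-hydrolysis state — the run-terminating arm of the kinetic
        race (s⁻¹).
    koff_apo : float
        Microtubule off-rate in the apo (no-nucleotide) state (s⁻¹).
    step_size : float
        Distance advanced per completed cycle (nm).
    k_off_th : float
        Reverse rate of tethered-head attachment (state 6 → 5), 0 by
        default: the reverse rate has not been measured.
    """

    kon_mt: float = 17.0
    kon_atp: float = 1.4
    k_hyd: float = FAST
    kon_th: float = 189.0
    koff_adp_fh: float = 354.0
    koff_rh: float = FAST
    k_detach_weak: float = 0.27
    koff_apo: float = 0.09
    step_size: float = STEP_SIZE_NM
    k_off_th: float = 0.0

    _RATE_FIELDS = (
        "kon_mt", "kon_atp", "k_hyd", "kon_th", "koff_adp_fh",
        "koff_rh", "k_detach_weak", "koff_apo", "k_off_th",
    )

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS:
            value = _parse_rate(getattr(self, name))
            if math.isnan(value) or value < 0:
                raise ValueError(f"rate {name!r} must be >= 0, got {value}")
            setattr(self, name, value)
        self.step_size = float(self.step_size)
        if not self.step_size > 0:
            raise ValueError(f"step_size must be > 0, got {self.step_size}")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        """Flat mapping with FAST rates rendered as the string ``"fast"``."""
        raw = asdict(self)
        return {k: _format_rate(v) if k != "step_size" else v for k, v in raw.items()}

    @classmethod
    def from_dict(cls, mapping: dict) -> "RateSet":
        return cls(**mapping)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RateSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RateSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def kif1a_rates() -> RateSet:
    """Measured KIF1A rate set (saturating-ATP motility conditions)."""
    return RateSet()


def kinesin1_rates() -> RateSet:
    """Kinesin-1 comparison rate set (literature values).

    The apo-state off-rate is not part of the comparative data set and is
    left at 0 (unused by the stepping simulation).
    """
    return RateSet(
        kon_mt=1.1,
        kon_atp=1.2,
        k_hyd=281.0,
        kon_th=216.0,
        koff_adp_fh=367.0,
        koff_rh=154.0,
        k_detach_weak=2.0,
        koff_apo=0.0,
    )
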