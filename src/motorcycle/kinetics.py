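"""Fitting of stopped-flow transients and concentration-dependence curves.

Stopped-flow fluorescence transients are modelled as sums of exponentials,

    s(t) = offset + Σ_i a_i · exp(−k_i t),

fit on t ≥ t_start, where t_start defaults to the 2-ms instrument dead
time. Observed rates (k_obs) as a function of reactant concentration are
then fit either linearly (pseudo-first-order binding:
k_obs = k_on·c + k_off) or with a saturation hyperbola
(rate = baseline + (k_max − baseline)·c/(K_half + c)); dwell-time
distributions from single-molecule assays are fit with an exponential
cumulative distribution whose inverse time constant is the off-rate.

All fitters are deterministic: initial guesses are derived from the data
by fixed rules (log-linear regression for exponentials, data extrema for
hyperbolae).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import statsmodels.api as sm
from scipy import optimize
from sklearn.base import BaseEstimator

from .cycle import OffRateCurveParams

__all__ = [
    "Trace",
    "TransientFit",
    "SaturationFit",
    "FitError",
    "ExponentialTransientFitter",
    "LinearRateFitter",
    "SaturationCurveFitter",
    "DwellTimeFitter",
    "OffRateCurveFitter",
    "fit_exponential",
    "fit_linear_kobs",
    "fit_saturation",
    "fit_dwell_times",
    "fit_off_rate_vs_adp",
    "half_site_amplitude_ratio",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass
class Trace:
    """A stopped-flow time series.

    ``meta`` carries the condition label and the instrument dead time
    (seconds); samples earlier than the dead time are retained in the
    arrays but should be excluded from fits via ``t_start``.
    """

    time_s: np.ndarray
    signal: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.time_s) < 10:
            raise ValueError("a trace needs at least 10 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace time must be strictly increasing")
        if len(self.time_s) != len(self.signal):
            raise ValueError("time and signal must have equal length")

    @property
    def dead_time_s(self) -> float:
        return float(self.meta.get("dead_time_s", 0.0))

    def pre_dead_time_mask(self) -> np.ndarray:
        """Boolean mask of samples acquired before the dead time."""
        return self.time_s < self.dead_time_s


@dataclass(frozen=True)
class TransientFit:
    """Multi-exponential fit result; phases are sorted fast-first."""

    phases: Tuple[Tuple[float, float], ...]  # (rate per s, amplitude)
    offset: float
    t_start_s: float
    rss: float
    flat: bool = False  # amplitude ~ 0: degenerate trace

    @property
    def rates(self) -> Tuple[float, ...]:
        return tuple(k for k, _ in self.phases)

    @property
    def amplitudes(self) -> Tuple[float, ...]:
        return tuple(a for _, a in self.phases)

    @property
    def k_obs(self) -> float:
        """Observed rate: the fast phase by convention."""
        return self.phases[0][0]

    @property
    def total_amplitude(self) -> float:
        return float(sum(abs(a) for a in self.amplitudes))


def _init_single_exponential(
    t: np.ndarray, y: np.ndarray
) -> Tuple[float, float, float]:
    """Deterministic (k, a, offset) starting values by log-linear regression."""
    offset0 = float(np.mean(y[-max(3, len(y) // 10):]))
    resid = y - offset0
    amp0 = float(resid[0])
    sign = 1.0 if amp0 >= 0 else -1.0
    mag = np.abs(resid)
    usable = mag > 0.02 * max(mag.max(), 1e-300)
    if usable.sum() >= 3:
        slope, intercept = np.polyfit(t[usable], np.log(mag[usable]), 1)
        k0 = max(-float(slope), 1e-9)
        a0 = sign * math.exp(float(intercept))
    else:
        span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        k0, a0 = 3.0 / span, amp0
    return k0, a0, offset0


class ExponentialTransientFitter(BaseEstimator):
    """Least-squares fit of ``offset + Σ a_i exp(−k_i t)`` on ``t >= t_start``.

    Parameters
    ----------
    n_phases : {1, 2}
        Number of exponential phases.
    t_start : float
        Fit start time in seconds; defaults to the 2-ms stopped-flow
        instrument dead time.

    Attributes
    ----------
    rates_, amplitudes_ : tuple
        Fitted phases sorted fast-first; amplitudes refer to t = 0.
    offset_ : float
    rss_ : float
    fit_ : TransientFit
    """

    def __init__(self, n_phases: int = 1, t_start: float = 0.002):
        self.n_phases = n_phases
        self.t_start = t_start

    # ------------------------------------------------------------------
    def _model(self, params: lmfit.Parameters, t: np.ndarray) -> np.ndarray:
        out = np.full_like(t, params["offset"].value)
        for i in range(self.n_phases):
            out = out + params[f"a{i}"] * np.exp(-params[f"k{i}"] * t)
        return out

    def fit(self, trace, signal: Optional[Sequence] = None
            ) -> "ExponentialTransientFitter":
        """Fit a :class:`Trace`, or arrays ``fit(time_s, signal)``."""
        if self.n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if signal is not None:
            trace = Trace(np.asarray(trace, float), np.asarray(signal, float))
        t_all, y_all = trace.time_s, trace.signal
        sel = t_all >= self.t_start
        t, y = t_all[sel], y_all[sel]
        if len(t) < 3 * self.n_phases + 1:
            raise ValueError("not enough samples after t_start to fit")

        if float(np.ptp(y)) == 0.0:  # degenerate flat trace
            self._finish(((1.0, 0.0),) * self.n_phases, float(y[0]), 0.0,
                         flat=True)
            return self

        k0, a0, offset0 = _init_single_exponential(t, y)
        params = lmfit.Parameters()
        params.add("offset", value=offset0)
        params.add("k0", value=k0, min=1e-12)
        params.add("a0", value=a0)
        if self.n_phases == 2:
            # sequential model building: start from the single-phase
            # solution plus a small slow phase, so single-phase data keeps
            # a negligible second amplitude instead of a split rate
            single = lmfit.minimize(
                lambda p: self._single_resid(p, t, y), params, method="leastsq"
            )
            params = single.params.copy()
            params.add("k1", value=max(params["k0"].value / 10.0, 1e-9),
                       min=1e-12)
            params.add("a1", value=0.05 * params["a0"].value)

        result = lmfit.minimize(
            lambda p: self._model(p, t) - y, params, method="leastsq"
        )
        if not result.success:
            raise FitError(f"exponential fit failed: {result.message}")
        p = result.params
        phases = sorted(
            ((float(p[f"k{i}"].value), float(p[f"a{i}"].value))
             for i in range(self.n_phases)),
            key=lambda ka: -ka[0],
        )
        rss = float(np.sum(np.asarray(result.residual) ** 2))
        total_amp = sum(abs(a) for _, a in phases)
        flat = total_amp < 1e-9 * max(abs(float(np.mean(y))), 1.0)
        self._finish(tuple(phases), float(p["offset"].value), rss, flat=flat)
        self.result_ = result
        return self

    @staticmethod
    def _single_resid(params, t, y):
        return params["offset"] + params["a0"] * np.exp(-params["k0"] * t) - y

    def _finish(self, phases, offset, rss, flat=False) -> None:
        self.fit_ = TransientFit(
            phases=phases, offset=offset, t_start_s=self.t_start, rss=rss,
            flat=flat,
        )
        self.rates_ = self.fit_.rates
        self.amplitudes_ = self.fit_.amplitudes
        self.offset_ = offset
        self.rss_ = rss

    def predict(self, time_s: Sequence[float]) -> np.ndarray:
        t = np.asarray(time_s, float)
        out = np.full_like(t, self.offset_)
        for k, a in self.fit_.phases:
            out = out + a * np.exp(-k * t)
        return out


class LinearRateFitter(BaseEstimator):
    """OLS fit of k_obs = slope·c + intercept (pseudo-first-order binding).

    The slope is the second-order on-rate (μM⁻¹ s⁻¹) and the intercept the
    off-rate (s⁻¹). Standard errors come from the OLS covariance.
    """

    def fit(self, conc_um: Sequence[float], kobs: Sequence[float]
            ) -> "LinearRateFitter":
        c = np.asarray(conc_um, float)
        k = np.asarray(kobs, float)
        if len(np.unique(c)) < 2:
            raise ValueError("need at least 2 distinct concentrations")
        res = sm.OLS(k, sm.add_constant(c)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.intercept_se_ = float(res.bse[0])
        self.slope_se_ = float(res.bse[1])
        self.result_ = res
        return self

    def predict(self, conc_um: Sequence[float]) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(conc_um, float)


@dataclass(frozen=True)
class SaturationFit:
    """Hyperbolic (Michaelis–Menten-type) saturation fit result."""

    kmax: float  # s⁻¹
    k_half: float  # μM (K_0.5 / K_m / K_D)
    baseline: float  # s⁻¹ (0 unless fit with a baseline)
    kmax_se: float
    k_half_se: float
    baseline_se: float
    extrapolated: bool  # k_half outside the sampled concentration range

    def ci95(self, name: str) -> Tuple[float, float]:
        value = getattr(self, name)
        se = getattr(self, f"{name}_se")
        return (value - 1.96 * se, value + 1.96 * se)


class SaturationCurveFitter(BaseEstimator):
    """Weighted least-squares fit of a saturation hyperbola.

    rate(c) = baseline + (kmax − baseline) · c / (k_half + c)

    with ``baseline`` fixed at 0 unless ``with_baseline=True`` (the form
    used for off-rate-vs-[ADP] curves, where the baseline is the apo-state
    rate). ``sample_weight`` follows the 1/SEM convention of weighted
    enzyme-kinetics fits; omitted or zero SEMs mean equal weights.
    """

    def __init__(self, with_baseline: bool = False):
        self.with_baseline = with_baseline

    @staticmethod
    def _model(c, kmax, k_half, baseline):
        return baseline + (kmax - baseline) * c / (k_half + c)

    def fit(self, conc_um: Sequence[float], rate: Sequence[float],
            sample_weight: Optional[Sequence[float]] = None
            ) -> "SaturationCurveFitter":
        c = np.asarray(conc_um, float)
        r = np.asarray(rate, float)
        if len(np.unique(c)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        sigma = None
        if sample_weight is not None:
            wgt = np.asarray(sample_weight, float)
            if np.any(wgt > 0) and not np.allclose(wgt, wgt[0]):
                sigma = 1.0 / np.where(wgt > 0, wgt, wgt[wgt > 0].min())
        # deterministic initialisation: plateau at the max rate, K at the
        # median sampled concentration
        kmax0 = float(r.max()) if r.max() > 0 else 1.0
        khalf0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
        base0 = float(r.min()) if self.with_baseline else 0.0

        if self.with_baseline:
            def f(cv, kmax, k_half, baseline):
                return self._model(cv, kmax, k_half, baseline)
            p0 = [kmax0, khalf0, base0]
            lower = [0.0, 1e-12, 0.0]
        else:
            def f(cv, kmax, k_half):
                return self._model(cv, kmax, k_half, 0.0)
            p0 = [kmax0, khalf0]
            lower = [0.0, 1e-12]
        try:
            popt, pcov = optimize.curve_fit(
                f, c, r, p0=p0, sigma=sigma, bounds=(lower, np.inf),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise FitError(f"saturation fit failed: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        kmax, k_half = float(popt[0]), float(popt[1])
        baseline = float(popt[2]) if self.with_baseline else 0.0
        base_se = float(perr[2]) if self.with_baseline else 0.0
        extrapolated = not (c.min() <= k_half <= c.max())
        if extrapolated:
            warnings.warn(
                f"fitted K_half = {k_half:.3g} uM lies outside the sampled "
                "concentration range; the plateau is an extrapolation",
                stacklevel=2,
            )
        self.kmax_ = kmax
        self.k_half_ = k_half
        self.baseline_ = baseline
        self.fit_ = SaturationFit(
            kmax=kmax, k_half=k_half, baseline=baseline,
            kmax_se=float(perr[0]), k_half_se=float(perr[1]),
            baseline_se=base_se, extrapolated=extrapolated,
        )
        return self

    def predict(self, conc_um: Sequence[float]) -> np.ndarray:
        return self._model(np.asarray(conc_um, float), self.kmax_,
                           self.k_half_, self.baseline_)


class DwellTimeFitter(BaseEstimator):
    """Exponential CDF fit to single-molecule dwell times.

    Fits ``F(t) = 1 − exp(−(t − t0)/τ)`` to the empirical CDF, where the
    location ``t0`` absorbs the detection dead time of camera-based assays
    (shortest detectable event). The off-rate is 1/τ.

    Attributes
    ----------
    mean_dwell_ : float
        Fitted exponential time constant τ (s).
    koff_ : float
        1 / mean_dwell_ (s⁻¹).
    t0_ : float
        Fitted detection offset (s).
    """

    def __init__(self, fit_offset: bool = True):
        self.fit_offset = fit_offset

    def fit(self, dwells_s: Sequence[float]) -> "DwellTimeFitter":
        x = np.sort(np.asarray(dwells_s, float))
        if len(x) < 10:
            raise ValueError("need at least 10 dwell times")
        if np.any(x < 0):
            raise ValueError("dwell times must be >= 0")
        # empirical CDF at the unique values (handles frame-quantized ties)
        uniq, counts = np.unique(x, return_counts=True)
        ecdf = np.cumsum(counts) / len(x)
        tau0 = max(float(np.mean(x) - x[0]), 1e-12)
        t00 = float(x[0])

        if self.fit_offset and len(uniq) >= 3:
            def model(t, tau, t0):
                return 1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau)
            popt, _ = optimize.curve_fit(
                model, uniq, ecdf, p0=[tau0, t00],
                bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000,
            )
            tau, t0 = float(popt[0]), float(popt[1])
        else:
            def model0(t, tau):
                return 1.0 - np.exp(-t / tau)
            popt, _ = optimize.curve_fit(
                model0, uniq, ecdf, p0=[max(float(np.mean(x)), 1e-12)],
                bounds=(1e-12, np.inf), maxfev=20000,
            )
            tau, t0 = float(popt[0]), 0.0
        self.mean_dwell_ = tau
        self.koff_ = 1.0 / tau
        self.t0_ = t0
        return self


class OffRateCurveFitter(BaseEstimator):
    """Fit of the microtubule off-rate vs [ADP] saturation curve.

    koff(c) = koff_apo + (koff_max − koff_apo)·c/(K_D + c). All three
    parameters are free; a zero-concentration point effectively pins
    koff_apo. The K_D of this curve is typically poorly conditioned with
    few concentrations — a wide confidence interval is expected, not an
    error.
    """

    def fit(self, conc_um: Sequence[float], koff: Sequence[float]
            ) -> "OffRateCurveFitter":
        c = np.asarray(conc_um, float)
        k = np.asarray(koff, float)
        if len(c) < 3:
            raise ValueError("need at least 3 points")

        def model(cv, apo, kmax, kd):
            return apo + (kmax - apo) * cv / (kd + cv)

        p0 = [float(k.min()), float(k.max()),
              float(np.median(c[c > 0])) if np.any(c > 0) else 1.0]
        try:
            popt, pcov = optimize.curve_fit(
                model, c, k, p0=p0,
                bounds=([0.0, 0.0, 1e-12], np.inf), maxfev=50000,
            )
        except RuntimeError as exc:
            raise FitError(f"off-rate curve fit failed: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        self.params_ = OffRateCurveParams(
            koff_apo=float(popt[0]), koff_max=float(popt[1]),
            k_d=float(popt[2]),
        )
        self.se_ = {"koff_apo": float(perr[0]), "koff_max": float(perr[1]),
                    "k_d": float(perr[2])}
        self.ci95_ = {
            name: (getattr(self.params_, name) - 1.96 * self.se_[name],
                   getattr(self.params_, name) + 1.96 * self.se_[name])
            for name in ("koff_apo", "koff_max", "k_d")
        }
        return self

    def predict(self, conc_um: Sequence[float]) -> np.ndarray:
        p = self.params_
        c = np.asarray(conc_um, float)
        return p.koff_apo + (p.koff_max - p.koff_apo) * c / (p.k_d + c)


# ---------------------------------------------------------------- wrappers

def fit_exponential(trace: Trace, n_phases: int = 1,
                    t_start: float = 0.002) -> TransientFit:
    """Exponential fit of a stopped-flow trace on t >= t_start."""
    return ExponentialTransientFitter(n_phases=n_phases, t_start=t_start).fit(
        trace).fit_


def fit_linear_kobs(conc_um: Sequence[float],
                    kobs: Sequence[float]) -> Dict[str, float]:
    """Linear k_obs-vs-concentration fit → on-rate (slope) and off-rate
    (intercept) with standard errors."""
    f = LinearRateFitter().fit(conc_um, kobs)
    return {
        "slope": f.slope_, "intercept": f.intercept_,
        "slope_se": f.slope_se_, "intercept_se": f.intercept_se_,
    }


def fit_saturation(conc_um: Sequence[float], rates: Sequence[float],
                   weights: Optional[Sequence[float]] = None,
                   with_baseline: bool = False) -> SaturationFit:
    """Weighted hyperbolic saturation fit → (kmax, K_half[, baseline])."""
    return SaturationCurveFitter(with_baseline=with_baseline).fit(
        conc_um, rates, sample_weight=weights).fit_


def fit_dwell_times(dwells_s: Sequence[float]) -> Dict[str, float]:
    """Exponential dwell-time fit → mean dwell and off-rate 1/mean."""
    f = DwellTimeFitter().fit(dwells_s)
    return {"mean_dwell_s": f.mean_dwell_, "koff_per_s": f.koff_,
            "t0_s": f.t0_}


def fit_off_rate_vs_adp(conc_um: Sequence[float],
                        koffs: Sequence[float]) -> OffRateCurveParams:
    """Off-rate-vs-[ADP] hyperbola fit → (koff_apo, koff_max, K_D)."""
    return OffRateCurveFitter().fit(conc_um, koffs).params_


def half_site_amplitude_ratio(fit_condition: TransientFit,
                              fit_reference: TransientFit) -> float:
    """Ratio of total fitted amplitudes, condition / reference.

    Used to compare how much bound nucleotide is released in a test
    condition relative to a saturating-ATP reference (half-site
    reactivity: a ratio near 0.5 means one of the two heads released its
    nucleotide).
    """
    ref = fit_reference.total_amplitude
    if ref <= 0:
        raise ZeroDivisionError("reference fit has zero total amplitude")
    return fit_condition.total_amplitude / ref
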