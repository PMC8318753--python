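"""Quantification of dynamic-enhancement curves and diffusion decays.

For a DCE time-signal curve S(t) with pre-contrast baseline S_pre the
percent enhancement is E(t) = 100 (S(t) - S_pre) / S_pre.  From it:

* steepest slope SS (%/s): the maximum finite-difference slope of E over
  consecutive samples — a wash-in rate linked to tumour microvessel density;
* washout ratio WR (%): 100 (E_peak - E_last) / E_peak, the late-phase
  fractional loss of enhancement;
* curve type (Schaefer-style): the relative late change
  r = (E_last - E_peak) / E_peak is thresholded at ±tol (default 10% of
  peak): r > +tol persistent, |r| <= tol plateau, r < -tol washout.

DWI signal at diffusion weighting b decays mono-exponentially,
S(b) = S0 exp(-b ADC); ADC (mm^2/s) is estimated by the least-squares line
through (b, ln S), which reduces to ln(S1/S2)/(b2-b1) for two b values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "TimeSignalCurve",
    "CurveParams",
    "DWISeries",
    "ADCResult",
    "percent_enhancement",
    "steepest_slope",
    "washout_ratio",
    "classify_curve",
    "curve_params",
    "compute_adc",
]


@dataclass(frozen=True)
class TimeSignalCurve:
    """Sampled enhancement curve; the first ``baseline_index_count`` samples
    are pre-contrast."""

    times: np.ndarray
    signal: np.ndarray
    baseline_index_count: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.size != s.size:
            raise ValidationError(f"times ({t.size}) and signal ({s.size}) lengths differ")
        if t.size < 4:
            raise ValidationError(f"curve needs >= 4 samples, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.baseline_index_count < 1 or self.baseline_index_count >= t.size:
            raise ValidationError(
                f"baseline_index_count must be in [1, n_samples), got {self.baseline_index_count}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValidationError("curve contains non-finite values")


@dataclass(frozen=True)
class CurveParams:
    """Quantitative descriptors of one enhancement curve."""

    ss: float                 # steepest slope, %/s
    wr: float | None          # washout ratio, %; None when peak <= 0
    curve_type: str | None    # persistent / plateau / washout; None when untypeable
    peak_time: float          # s
    peak_enhancement: float   # %

    def as_dict(self) -> dict:
        return {
            "ss_percent_per_s": self.ss,
            "wr_percent": self.wr,
            "curve_type": self.curve_type,
            "peak_time_s": self.peak_time,
            "peak_enhancement_percent": self.peak_enhancement,
        }


@dataclass(frozen=True)
class DWISeries:
    """Signals at increasing diffusion weightings b (s/mm^2)."""

    b_values: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "signals", s)
        if b.size != s.size:
            raise ValidationError(f"b_values ({b.size}) and signals ({s.size}) lengths differ")
        if b.size < 2:
            raise ValidationError("DWI series needs >= 2 b values")
        if np.any(b < 0):
            raise ValidationError("b_values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b_values must be strictly increasing")


@dataclass(frozen=True)
class ADCResult:
    adc: float        # mm^2/s
    s0_fit: float     # a.u.
    r_squared: float  # goodness of the log-linear fit


def percent_enhancement(curve: TimeSignalCurve) -> np.ndarray:
    """E(t) = 100 (S(t) - S_pre)/S_pre with S_pre the mean baseline signal."""
    s_pre = float(np.mean(curve.signal[: curve.baseline_index_count]))
    if s_pre <= 0:
        raise ValidationError(f"baseline signal must be positive, got mean {s_pre}")
    return 100.0 * (curve.signal - s_pre) / s_pre


def steepest_slope(curve: TimeSignalCurve) -> float:
    """Maximum consecutive-sample slope of the percent-enhancement series, %/s."""
    e = percent_enhancement(curve)
    return float(np.max(np.diff(e) / np.diff(curve.times)))


def _peak(curve: TimeSignalCurve) -> tuple[int, float, np.ndarray]:
    e = percent_enhancement(curve)
    k = int(np.argmax(e))
    return k, float(e[k]), e


def washout_ratio(curve: TimeSignalCurve) -> float:
    """WR = 100 (E_peak - E_last) / E_peak; requires positive peak enhancement."""
    _, e_peak, e = _peak(curve)
    if e_peak <= 0:
        raise UndefinedMetricError(f"WR undefined: peak enhancement {e_peak} <= 0")
    return 100.0 * (e_peak - e[-1]) / e_peak


def classify_curve(curve: TimeSignalCurve, tol: float = 10.0) -> str:
    """Schaefer-style typing by the relative late-phase change of enhancement.

    The initial peak is located as the enhancement maximum within the first
    half of the acquisition; a least-squares line is fitted to E(t) from
    that point to the end, and the relative late change

        r = 100 * (E_fit(t_end) - E_fit(t_peak)) / E_fit(t_peak)   [%]

    is thresholded: r > +tol persistent, |r| <= tol plateau, r < -tol
    washout.  The linear fit (rather than the single first/last samples)
    makes the type stable under sampling noise; on noiseless
    piecewise-linear curves it reproduces the pointwise late change
    exactly.
    """
    e = percent_enhancement(curve)
    t = curve.times
    early = t <= t[0] + 0.5 * (t[-1] - t[0])
    k = int(np.argmax(np.where(early, e, -np.inf)))
    if e[k] <= 0:
        raise UndefinedMetricError(
            f"curve type undefined: no positive enhancement in the early phase (max {e[k]:.3g})"
        )
    late = slice(k, None)
    slope, intercept = np.polyfit(t[late], e[late], 1)
    e_start = intercept + slope * t[k]
    e_end = intercept + slope * t[-1]
    if e_start <= 0:
        raise UndefinedMetricError("curve type undefined: fitted late-phase start is non-positive")
    r = 100.0 * (e_end - e_start) / e_start
    if r > tol:
        return "persistent"
    if r < -tol:
        return "washout"
    return "plateau"


def curve_params(curve: TimeSignalCurve, tol: float = 10.0) -> CurveParams:
    """SS, WR, type, peak time and peak enhancement in one report."""
    k, e_peak, _ = _peak(curve)
    try:
        wr = washout_ratio(curve)
        ctype = classify_curve(curve, tol)
    except UndefinedMetricError:
        wr, ctype = None, None
    return CurveParams(
        ss=steepest_slope(curve),
        wr=wr,
        curve_type=ctype,
        peak_time=float(curve.times[k]),
        peak_enhancement=e_peak,
    )


def compute_adc(series: DWISeries) -> ADCResult:
    """Log-linear least-squares ADC estimate.

    Fits ln S = ln S0 - b ADC over all b values; with two points this is the
    exact formula ADC = ln(S1/S2)/(b2 - b1).
    """
    s = series.signals
    if np.any(s <= 0):
        raise ValidationError("all DWI signals must be positive for the log-linear fit")
    b = series.b_values
    logs = np.log(s)
    slope, intercept = np.polyfit(b, logs, 1)
    fitted = intercept + slope * b
    ss_res = float(np.sum((logs - fitted) ** 2))
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ADCResult(adc=float(-slope), s0_fit=float(np.exp(intercept)), r_squared=min(r2, 1.0))
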