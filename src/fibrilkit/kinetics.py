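"""Kinetic feature extraction from aggregation traces and fibril length series.

ThT fluorescence traces are summarized with a Boltzmann sigmoid

    F(t) = F0 + (Fmax - F0) / (1 + exp(-(t - t_half) / tau_g))

from which the lag time follows the tangent-intercept convention
lag = t_half - 2 * tau_g and the maximal growth rate is
(Fmax - F0) / (4 * tau_g). Single-fibril elongation rates are the net length
change divided by the growth time, reported in nm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ThTTrace",
    "KineticFeatures",
    "FibrilLengthSeries",
    "ElongationRate",
    "boltzmann",
    "fit_sigmoid",
    "growth_rate_tirf",
]


@dataclass
class ThTTrace:
    """A ThT fluorescence time course (hours vs arbitrary units)."""

    time_h: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_h.shape != self.fluorescence.shape or self.time_h.ndim != 1:
            raise ValueError("time and fluorescence must be equal-length 1-D")
        if len(self.time_h) < 10:
            raise ValueError("ThT trace needs >= 10 points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass
class KineticFeatures:
    """Lag, growth rate and plateau of a sigmoidal aggregation trace."""

    lag_time: float
    growth_rate: float
    plateau: float
    baseline: float
    t_half: float
    tau_g: float
    converged: bool
    aggregating: bool

    def to_dict(self) -> dict:
        return {
            "lag_time_h": self.lag_time,
            "growth_rate_per_h": self.growth_rate,
            "plateau": self.plateau,
            "baseline": self.baseline,
            "t_half_h": self.t_half,
            "tau_g_h": self.tau_g,
            "converged": self.converged,
            "aggregating": self.aggregating,
        }


@dataclass
class FibrilLengthSeries:
    """Length of a single growing fibril over time (seconds vs micrometres)."""

    time_s: np.ndarray
    length_um: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.length_um = np.asarray(self.length_um, dtype=float)
        if self.time_s.shape != self.length_um.shape or self.time_s.ndim != 1:
            raise ValueError("time and length must be equal-length 1-D")
        if len(self.time_s) < 2:
            raise ValueError("need >= 2 points")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.length_um < 0):
            raise ValueError("lengths must be >= 0")


@dataclass
class ElongationRate:
    """Net single-fibril growth rate in nm/s."""

    rate_nm_per_s: float
    shrinking: bool

    def __float__(self) -> float:
        return self.rate_nm_per_s


def boltzmann(t, f0, fmax, t_half, tau_g):
    t = np.asarray(t, dtype=float)
    return f0 + (fmax - f0) / (1.0 + np.exp(-(t - t_half) / tau_g))


def _robust_sigma(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _non_aggregating(baseline: float) -> KineticFeatures:
    return KineticFeatures(
        lag_time=math.nan,
        growth_rate=math.nan,
        plateau=math.nan,
        baseline=baseline,
        t_half=math.nan,
        tau_g=math.nan,
        converged=False,
        aggregating=False,
    )


def fit_sigmoid(trace: ThTTrace) -> KineticFeatures:
    """Boltzmann fit of a ThT trace; flags flat or decreasing traces.

    A trace whose amplitude is below three times the robust noise level of
    its first 10% is classified non-aggregating and not force-fitted.
    """
    t, f = trace.time_h, trace.fluorescence
    n_head = max(3, len(t) // 10)
    baseline = float(np.median(f[:n_head]))
    noise = _robust_sigma(f[:n_head])
    noise_floor = max(noise, 1e-9 * max(1.0, float(np.max(np.abs(f)))))
    amplitude = float(np.median(f[-n_head:]) - baseline)

    if amplitude <= 3.0 * noise_floor:
        return _non_aggregating(baseline)

    fmax_init = float(np.median(f[-n_head:]))
    half_level = baseline + amplitude / 2.0
    above = np.where(f >= half_level)[0]
    t_half_init = float(t[above[0]]) if len(above) else float(np.median(t))
    tau_init = max((t[-1] - t[0]) / 20.0, 1e-3)

    try:
        popt, _ = curve_fit(
            boltzmann,
            t,
            f,
            p0=[baseline, fmax_init, t_half_init, tau_init],
            bounds=(
                [-np.inf, -np.inf, t[0] - (t[-1] - t[0]), 1e-6],
                [np.inf, np.inf, t[-1] + (t[-1] - t[0]), np.inf],
            ),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return KineticFeatures(
            lag_time=math.nan,
            growth_rate=math.nan,
            plateau=math.nan,
            baseline=baseline,
            t_half=math.nan,
            tau_g=math.nan,
            converged=False,
            aggregating=True,
        )

    f0_hat, fmax_hat, t_half_hat, tau_hat = popt
    if fmax_hat < f0_hat:
        return _non_aggregating(baseline)
    return KineticFeatures(
        lag_time=float(t_half_hat - 2.0 * tau_hat),
        growth_rate=float((fmax_hat - f0_hat) / (4.0 * tau_hat)),
        plateau=float(fmax_hat),
        baseline=float(f0_hat),
        t_half=float(t_half_hat),
        tau_g=float(tau_hat),
        converged=converged,
        aggregating=True,
    )


def growth_rate_tirf(series: FibrilLengthSeries) -> ElongationRate:
    """Net elongation rate: (final - initial length) / elapsed time, in nm/s.

    End of growth is the last point of the series.
    """
    dt = series.time_s[-1] - series.time_s[0]
    if dt <= 0:
        raise ValueError("zero elapsed time")
    d_len_um = series.length_um[-1] - series.length_um[0]
    rate = 1000.0 * d_len_um / dt  # um/s -> nm/s
    return ElongationRate(rate_nm_per_s=float(rate), shrinking=rate < 0)
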