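"""Two-state fibril dissolution in formic acid.

Band intensities from a dissolution titration are normalized to a fully
dissolved reference lane and fitted to

    y_diss(FA) = 100 / (1 + 10**(-m_fa * (fa50 - FA) / 1.36))

where fa50 is the dissolution midpoint (% v/v formic acid) and m_fa the
steepness on the 1.36-scaled convention (1.36 = 2.303 * R * T kcal/mol at
25 C), so the extrapolated dissolution free energy is dG = |m_fa| * fa50.
As printed, the exponent produces an increasing sigmoid only for negative
m_fa; the fit leaves m_fa unconstrained, requires the fitted curve to be
increasing in FA, and reports the absolute value alongside the signed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DissolutionSeries",
    "DissolutionFit",
    "NonIdentifiableError",
    "dissolution_model",
    "normalize_to_reference",
    "fit_dissolution",
    "predict_dissolution",
]

SCALE_KCAL = 1.36  # 2.303 * R * T at 25 C, kcal/mol


class NonIdentifiableError(ValueError):
    """Raised when the data contain no dissolution transition to fit."""


@dataclass
class DissolutionSeries:
    """%FA vs band intensity, with the normalization reference lane."""

    fa_percent: np.ndarray
    intensity: np.ndarray
    reference_fa: float = 98.0

    def __post_init__(self) -> None:
        self.fa_percent = np.asarray(self.fa_percent, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.fa_percent.shape != self.intensity.shape or self.fa_percent.ndim != 1:
            raise ValueError("fa_percent and intensity must be equal-length 1-D")
        if np.any(self.fa_percent < 0) or np.any(self.fa_percent > 100):
            raise ValueError("fa_percent must lie in [0, 100]")
        if not np.any(np.isclose(self.fa_percent, self.reference_fa)):
            raise ValueError(
                f"reference lane at {self.reference_fa}% FA not present in series"
            )


@dataclass
class DissolutionFit:
    """Fitted midpoint, steepness and extrapolated free energy."""

    fa50: float
    m_fa: float  # signed, as fitted (negative for an increasing curve)
    dG: float  # |m_fa| * fa50, kcal/mol
    fa50_se: float
    m_fa_se: float
    dG_se: float
    residual_rms: float

    @property
    def m_fa_abs(self) -> float:
        return abs(self.m_fa)

    def to_dict(self) -> dict:
        return {
            "fa50": self.fa50,
            "m_fa": self.m_fa,
            "m_fa_abs": self.m_fa_abs,
            "dG": self.dG,
            "fa50_se": self.fa50_se,
            "m_fa_se": self.m_fa_se,
            "dG_se": self.dG_se,
            "residual_rms": self.residual_rms,
        }


def dissolution_model(fa, fa50: float, m_fa: float):
    """Two-state dissolution curve; exactly 50 at fa == fa50."""
    fa = np.asarray(fa, dtype=float)
    return 100.0 / (1.0 + 10.0 ** (-m_fa * (fa50 - fa) / SCALE_KCAL))


def normalize_to_reference(series: DissolutionSeries) -> np.ndarray:
    """Percent dissolved: 100 * intensity / intensity(reference lane)."""
    ref_mask = np.isclose(series.fa_percent, series.reference_fa)
    ref_intensity = float(np.mean(series.intensity[ref_mask]))
    if ref_intensity <= 0:
        raise ValueError(
            f"reference lane intensity must be > 0, got {ref_intensity}"
        )
    return 100.0 * series.intensity / ref_intensity


def fit_dissolution(fa, y) -> DissolutionFit:
    """Least-squares fit of (fa50, m_fa) to percent-dissolved data."""
    fa = np.asarray(fa, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(fa) < 4:
        raise ValueError("need >= 4 points spanning the transition")
    if np.all(y < 10.0) or np.all(y > 90.0):
        raise NonIdentifiableError(
            "no dissolution transition in data (all ~0 or all ~100)"
        )

    fa50_init = float(fa[np.argmin(np.abs(y - 50.0))])
    popt, pcov = curve_fit(
        dissolution_model, fa, y, p0=[fa50_init, -0.5], maxfev=20000
    )
    fa50_hat, m_hat = popt
    if m_hat > 0:
        raise NonIdentifiableError(
            "fitted curve decreases with FA; expected dissolution to increase"
        )
    perr = np.sqrt(np.diag(pcov))
    resid = y - dissolution_model(fa, *popt)
    dg = abs(m_hat) * fa50_hat
    # first-order propagation, ignoring the (typically small) covariance term
    dg_se = math.hypot(abs(m_hat) * perr[0], fa50_hat * perr[1])
    return DissolutionFit(
        fa50=float(fa50_hat),
        m_fa=float(m_hat),
        dG=float(dg),
        fa50_se=float(perr[0]),
        m_fa_se=float(perr[1]),
        dG_se=float(dg_se),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def predict_dissolution(fit: DissolutionFit, fa) -> np.ndarray:
    """Evaluate the fitted dissolution curve at the given %FA values."""
    return dissolution_model(fa, fit.fa50, fit.m_fa)
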