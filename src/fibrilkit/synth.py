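"""Seeded synthetic datasets with the statistical structure each fitter assumes.

Every generator is deterministic given its NoiseSpec seed, reduces to the
exact noiseless forward model at sigma = 0, and produces objects that
round-trip through the package's CSV readers. A single top-level seed can be
fanned out to independent per-dataset streams with :func:`spawn_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exchange import DESTDataset, ExchangeParameters, SaturationScheme, simulate_profile
from .kinetics import FibrilLengthSeries, ThTTrace, boltzmann
from .relaxation import DecaySeries
from .stability import DissolutionSeries, dissolution_model

__all__ = [
    "NoiseSpec",
    "spawn_seeds",
    "gen_dest_dataset",
    "gen_decay",
    "gen_dissolution",
    "gen_tht",
    "gen_fibril_growth",
]

_KINDS = ("additive-gaussian", "multiplicative-gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: kind, scale and seed.

    ``sigma`` is in signal units for additive-gaussian noise and a relative
    fraction for multiplicative-gaussian noise.
    """

    kind: str = "additive-gaussian"
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0.0:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sigma, size=values.shape)
        if self.kind == "additive-gaussian":
            return values + eps
        return values * (1.0 + eps)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one top-level seed out into n independent child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def gen_dest_dataset(
    params: ExchangeParameters, scheme: SaturationScheme, noise: NoiseSpec
) -> DESTDataset:
    """Forward-model DEST profiles plus noise on the attenuation ratio."""
    clean = simulate_profile(params, scheme)
    table = clean.table.copy()
    noisy = np.clip(noise.apply(table["attenuation"].to_numpy()), -0.05, 1.05)
    table["attenuation"] = noisy
    table["sigma"] = noise.sigma if noise.sigma > 0 else np.nan
    return DESTDataset(table)


def gen_decay(
    r2: float,
    i0: float = 1.0,
    delays: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> DecaySeries:
    """Exponential decay series; default schedule is 8 delays in [0, 250] ms."""
    if delays is None:
        delays = np.linspace(0.0, 0.25, 8)
    delays = np.asarray(delays, dtype=float)
    clean = i0 * np.exp(-r2 * delays)
    return DecaySeries(delays=delays, intensities=noise.apply(clean))


def gen_dissolution(
    fa50: float,
    m_fa: float,
    lanes: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    reference_fa: float = 98.0,
) -> DissolutionSeries:
    """Sigmoidal dissolution lanes; the reference lane is always included."""
    if lanes is None:
        lanes = np.array([0.0, 30.0, 45.0, 50.0, 55.0, 57.5, 60.0,
                          62.5, 65.0, 70.0, 80.0, 98.0])
    lanes = np.asarray(lanes, dtype=float)
    if not np.any(np.isclose(lanes, reference_fa)):
        lanes = np.append(lanes, reference_fa)
    clean = dissolution_model(lanes, fa50, m_fa) / 100.0  # arbitrary-unit bands
    return DissolutionSeries(
        fa_percent=lanes,
        intensity=np.clip(noise.apply(clean), 0.0, None),
        reference_fa=reference_fa,
    )


def gen_tht(
    lag_h: float,
    growth_rate: float,
    plateau: float,
    baseline: float = 0.0,
    duration_h: float = 60.0,
    step_h: float = 1.0 / 6.0,
    noise: NoiseSpec = NoiseSpec(),
    metadata: dict | None = None,
) -> ThTTrace:
    """Boltzmann ThT trace parameterized by lag time and maximal growth rate.

    The sigmoid parameters follow from the tangent-intercept lag convention:
    tau_g = amplitude / (4 * growth_rate) and t_half = lag + 2 * tau_g. A
    zero-amplitude (plateau == baseline) trace is flat by construction.
    """
    t = np.arange(0.0, duration_h + step_h / 2, step_h)
    amplitude = plateau - baseline
    if amplitude == 0.0:
        clean = np.full_like(t, baseline)
    else:
        if growth_rate <= 0:
            raise ValueError("growth_rate must be > 0 for an aggregating trace")
        tau_g = amplitude / (4.0 * growth_rate)
        t_half = lag_h + 2.0 * tau_g
        clean = boltzmann(t, baseline, plateau, t_half, tau_g)
    return ThTTrace(
        time_h=t, fluorescence=noise.apply(clean), metadata=dict(metadata or {})
    )


def gen_fibril_growth(
    rate_nm_per_s: float,
    duration_s: float = 3.0 * 3600.0,
    frame_interval_s: float = 30.0,
    length0_um: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> FibrilLengthSeries:
    """Linear single-fibril growth imaged at a fixed frame interval."""
    t = np.arange(0.0, duration_s + frame_interval_s / 2, frame_interval_s)
    clean = length0_um + rate_nm_per_s * 1e-3 * t  # nm/s -> um/s
    return FibrilLengthSeries(
        time_s=t, length_um=np.clip(noise.apply(clean), 0.0, None)
    )
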