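"""Default acquisition scheme and per-variant exchange-parameter presets.

The ``ntnu800`` profile mirrors the 800 MHz acquisition the fitters default
to: 700 ms continuous-wave saturation at RF fields of 180 and 350 Hz over 15
offsets spanning +35 to -35 kHz from the water carrier, with the visible
amide envelope placed 3.525 ppm (2820 Hz) downfield of water. Variant
presets share kon_app = 4.3 s^-1, R1 = 3 s^-1, R2 = 9.1 s^-1 and
R2_dark = 31,000 s^-1 and differ only in koff (wt 900, dm 1900, tm 7000
s^-1); qm has no detectable bound state.
"""

from __future__ import annotations

from .exchange import ExchangeParameters, SaturationScheme

__all__ = [
    "NTNU800",
    "default_scheme",
    "variant_parameters",
    "VARIANT_KOFF",
]

NTNU800 = {
    "kon_app": 4.3,
    "r1_free": 3.0,
    "r2_free": 9.1,
    "r1_dark": 3.0,
    "r2_dark": 31000.0,
    "spectrometer_mhz": 800.0,
    "amide_center_ppm": 8.225,  # center of the 7.85-8.6 ppm window
    "water_ppm": 4.7,
    "sat_time": 0.7,
    "rf_fields": (180.0, 350.0),
    "n_offsets": 15,
    "max_offset_hz": 35000.0,
}

VARIANT_KOFF = {"wt": 900.0, "dm": 1900.0, "tm": 7000.0}


def carrier_offset_hz(profile: dict = NTNU800) -> float:
    """Effective amide resonance offset from water, in Hz."""
    return (profile["amide_center_ppm"] - profile["water_ppm"]) * profile[
        "spectrometer_mhz"
    ]


def default_scheme(profile: dict = NTNU800) -> SaturationScheme:
    import numpy as np

    return SaturationScheme(
        sat_time=profile["sat_time"],
        rf_fields=profile["rf_fields"],
        offsets=tuple(
            np.linspace(
                profile["max_offset_hz"],
                -profile["max_offset_hz"],
                profile["n_offsets"],
            )
        ),
    )


def variant_parameters(variant: str, **overrides) -> ExchangeParameters:
    """Exchange parameters for a named variant scenario (wt, dm, tm, qm)."""
    variant = variant.lower()
    delta = carrier_offset_hz()
    base = dict(
        kon_app=NTNU800["kon_app"],
        r1_free=NTNU800["r1_free"],
        r2_free=NTNU800["r2_free"],
        r1_dark=NTNU800["r1_dark"],
        r2_dark=NTNU800["r2_dark"],
        delta_free=delta,
        delta_dark=delta,
    )
    if variant in VARIANT_KOFF:
        base["koff"] = VARIANT_KOFF[variant]
    elif variant == "qm":
        # no transiently bound state: kon_app = 0 (koff value is inert)
        base["kon_app"] = 0.0
        base["koff"] = 1000.0
    else:
        raise ValueError(f"unknown variant {variant!r}; expected wt/dm/tm/qm")
    base.update(overrides)
    return ExchangeParameters(**base)
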