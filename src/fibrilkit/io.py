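"""CSV readers and writers for the fixed column dialects used across the kit.

Dialects (header required):
  DEST:        rf_field_hz, offset_hz, attenuation[, sigma]
  relaxation:  delay_s, intensity
  dissolution: fa_percent, intensity
  ThT:         time_h, fluorescence[, extra metadata columns]
  TIRF:        time_s, length_um
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exchange import DESTDataset
from .kinetics import FibrilLengthSeries, ThTTrace
from .relaxation import DecaySeries, RecoverySeries
from .stability import DissolutionSeries

__all__ = [
    "read_dest_csv",
    "write_dest_csv",
    "read_decay_csv",
    "read_recovery_csv",
    "write_relaxation_csv",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_tht_csv",
    "write_tht_csv",
    "read_tirf_csv",
    "write_tirf_csv",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_dest_csv(path) -> DESTDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["rf_field_hz", "offset_hz", "attenuation"], path)
    if "sigma" not in df.columns:
        df["sigma"] = np.nan
    return DESTDataset(df[["rf_field_hz", "offset_hz", "attenuation", "sigma"]])


def write_dest_csv(dataset: DESTDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def read_decay_csv(path) -> DecaySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["delay_s", "intensity"], path)
    return DecaySeries(df["delay_s"].to_numpy(), df["intensity"].to_numpy())


def read_recovery_csv(path) -> RecoverySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["delay_s", "intensity"], path)
    return RecoverySeries(df["delay_s"].to_numpy(), df["intensity"].to_numpy())


def write_relaxation_csv(series, path) -> None:
    pd.DataFrame(
        {"delay_s": series.delays, "intensity": series.intensities}
    ).to_csv(path, index=False)


def read_dissolution_csv(path, reference_fa: float = 98.0) -> DissolutionSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["fa_percent", "intensity"], path)
    return DissolutionSeries(
        df["fa_percent"].to_numpy(), df["intensity"].to_numpy(), reference_fa
    )


def write_dissolution_csv(series: DissolutionSeries, path) -> None:
    pd.DataFrame(
        {"fa_percent": series.fa_percent, "intensity": series.intensity}
    ).to_csv(path, index=False)


def read_tht_csv(path) -> ThTTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_h", "fluorescence"], path)
    meta_cols = [c for c in df.columns if c not in ("time_h", "fluorescence")]
    metadata = {c: df[c].iloc[0] for c in meta_cols} if meta_cols else {}
    return ThTTrace(
        df["time_h"].to_numpy(), df["fluorescence"].to_numpy(), metadata
    )


def write_tht_csv(trace: ThTTrace, path) -> None:
    df = pd.DataFrame({"time_h": trace.time_h, "fluorescence": trace.fluorescence})
    for k, v in trace.metadata.items():
        df[k] = v
    df.to_csv(path, index=False)


def read_tirf_csv(path) -> FibrilLengthSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "length_um"], path)
    return FibrilLengthSeries(df["time_s"].to_numpy(), df["length_um"].to_numpy())


def write_tirf_csv(series: FibrilLengthSeries, path) -> None:
    pd.DataFrame(
        {"time_s": series.time_s, "length_um": series.length_um}
    ).to_csv(path, index=False)
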