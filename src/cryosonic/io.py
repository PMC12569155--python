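"""Plain-text and TIFF input/output for the analysis chain.

File conventions:

* axial scans — CSV with columns ``z_mm, pressure_pa, voltage_v, power_w``
* temperature traces — CSV with columns ``time_s, temp_c`` (optional
  ``power_w`` column; otherwise pass the power explicitly)
* waveforms — CSV with columns ``t_s, volts`` plus a JSON sidecar
  (``sample_rate``, ``frequency``) or explicit keyword arguments
* fluorescence images — 16-bit greyscale TIFF, with a manifest CSV
  (``condition, timepoint_h, replicate, fda_path, pi_path``)
* model/simulator configs — YAML mappings of constructor fields
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acoustic_field import AxialScan, TubeFieldModel
from .hydrophone_calibration import ToneBurstRecord
from .rewarming_kinetics import TemperatureTrace
from .synthetic_data import RewarmSimConfig
from .viability_analysis import FluorescencePair

__all__ = [
    "read_axial_scan",
    "write_axial_scan",
    "read_temperature_trace",
    "write_temperature_trace",
    "read_waveform",
    "write_waveform",
    "read_image_pair",
    "write_image_pair",
    "read_manifest",
    "load_tube_field_model",
    "load_rewarm_config",
]


def read_axial_scan(path: str | Path) -> AxialScan:
    df = pd.read_csv(path)
    volts = float(df["voltage_v"].iloc[0]) if "voltage_v" in df else float("nan")
    power = float(df["power_w"].iloc[0]) if "power_w" in df else None
    return AxialScan(
        positions_mm=df["z_mm"].to_numpy(float),
        amplitudes_pa=df["pressure_pa"].to_numpy(float),
        drive_voltage=volts,
        electrical_power=power,
    )


def write_axial_scan(scan: AxialScan, path: str | Path) -> None:
    pd.DataFrame(
        {
            "z_mm": scan.positions_mm,
            "pressure_pa": scan.amplitudes_pa,
            "voltage_v": scan.drive_voltage,
            "power_w": np.nan if scan.electrical_power is None else scan.electrical_power,
        }
    ).to_csv(path, index=False)


def read_temperature_trace(
    path: str | Path, power_w: float | None = None, **labels
) -> TemperatureTrace:
    df = pd.read_csv(path)
    if power_w is None:
        power_w = float(df["power_w"].iloc[0]) if "power_w" in df else 0.0
    return TemperatureTrace(
        times_s=df["time_s"].to_numpy(float),
        temperatures_c=df["temp_c"].to_numpy(float),
        power_w=power_w,
        labels=labels,
    )


def write_temperature_trace(trace: TemperatureTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times_s,
            "temp_c": trace.temperatures_c,
            "power_w": trace.power_w,
        }
    ).to_csv(path, index=False)


def read_waveform(
    path: str | Path,
    sample_rate: float | None = None,
    frequency: float | None = None,
) -> ToneBurstRecord:
    """Read a ``t_s, volts`` CSV; metadata from a ``.json`` sidecar if present."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sample_rate = sample_rate or meta.get("sample_rate")
        frequency = frequency or meta.get("frequency")
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    if frequency is None:
        raise ValueError("drive frequency required (sidecar or argument)")
    return ToneBurstRecord(
        samples=df["volts"].to_numpy(float),
        sample_rate=float(sample_rate),
        drive_frequency=float(frequency),
    )


def write_waveform(record: ToneBurstRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.samples.size) / record.sample_rate
    pd.DataFrame({"t_s": t, "volts": record.samples}).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(
            {"sample_rate": record.sample_rate, "frequency": record.drive_frequency}
        )
    )


def read_image_pair(
    fda_path: str | Path,
    pi_path: str | Path,
    condition: str = "",
    timepoint_h: float = 0.0,
    replicate: int = 0,
) -> FluorescencePair:
    return FluorescencePair(
        fda_image=tifffile.imread(fda_path),
        pi_image=tifffile.imread(pi_path),
        condition=condition,
        timepoint_h=timepoint_h,
        replicate=replicate,
    )


def write_image_pair(
    pair: FluorescencePair, fda_path: str | Path, pi_path: str | Path
) -> None:
    tifffile.imwrite(fda_path, np.asarray(pair.fda_image, dtype=np.uint16))
    tifffile.imwrite(pi_path, np.asarray(pair.pi_image, dtype=np.uint16))


def read_manifest(path: str | Path) -> list[FluorescencePair]:
    """Read a dataset manifest CSV and load every referenced image pair."""
    path = Path(path)
    df = pd.read_csv(path)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            read_image_pair(
                path.parent / row["fda_path"],
                path.parent / row["pi_path"],
                condition=str(row["condition"]),
                timepoint_h=float(row["timepoint_h"]),
                replicate=int(row["replicate"]),
            )
        )
    return pairs


def load_tube_field_model(path: str | Path) -> TubeFieldModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return TubeFieldModel(**cfg)


def load_rewarm_config(path: str | Path) -> RewarmSimConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "melt_window_c" in cfg:
        cfg["melt_window_c"] = tuple(cfg["melt_window_c"])
    return RewarmSimConfig(**cfg)
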