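"""Readers and writers: AMBER mdout DV/DL extraction, two-column
tabular series, canonical JSON results and YAML configuration."""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import GradientSeries, ProtocolConfig

__all__ = [
    "read_series",
    "read_series_csv",
    "read_series_mdout",
    "write_series_csv",
    "write_record",
    "read_record",
    "load_protocol_config",
]

_DVDL_RE = re.compile(r"DV/DL\s*=\s*(-?[\d.]+(?:[eE][+-]?\d+)?)")
_AVERAGES_RE = re.compile(r"A\s+V\s+E\s+R\s+A\s+G\s+E\s+S")


def read_series_mdout(
    path: str | Path, lambda_value: float, sampling_interval: float
) -> GradientSeries:
    """Extract instantaneous DV/DL values from an AMBER mdout file.

    Collects each "DV/DL = <value>" record in order, stopping at the
    trailing averages / fluctuations blocks. The output cadence is not
    recorded in mdout, so the sampling interval must be supplied.
    """
    text = Path(path).read_text()
    body = _AVERAGES_RE.split(text)[0]  # drop averages + fluctuations blocks
    values = [float(m.group(1)) for m in _DVDL_RE.finditer(body)]
    if not values:
        raise ValueError(f"{path}: no DV/DL records found — not a TI mdout output")
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite DV/DL value")
    return GradientSeries(
        lambda_value=lambda_value,
        sampling_interval=sampling_interval,
        values=arr,
        label=str(path),
    )


def read_series_csv(
    path: str | Path, lambda_value: float, sampling_interval: float | None = None
) -> GradientSeries:
    """Read a two-column (time_ns, dvdl_kcal_mol) series with a header.

    The time column must be uniformly spaced (validated to 1e-6 ns);
    an explicit ``sampling_interval`` overrides the inferred spacing.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_ns, dvdl_kcal_mol)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError(f"{path}: empty series")
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(t)):
        raise ValueError(f"{path}: non-finite entries")
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - dt[0]) > 1e-6)[0]
        if bad.size:
            raise ValueError(f"{path}: nonuniform sampling at row {int(bad[0]) + 1}")
        inferred = float(dt[0])
    else:
        inferred = None
    dt_final = sampling_interval if sampling_interval is not None else inferred
    if dt_final is None or dt_final <= 0:
        raise ValueError(f"{path}: cannot infer sampling interval; pass it explicitly")
    return GradientSeries(
        lambda_value=lambda_value,
        sampling_interval=dt_final,
        values=v,
        start_time=float(t[0]) - dt_final if t.size else 0.0,
        label=str(path),
    )


def read_series(
    path: str | Path,
    lambda_value: float,
    sampling_interval: float | None = None,
    dialect: str | None = None,
) -> GradientSeries:
    """Read a gradient series, auto-detecting the dialect.

    A file containing a "DV/DL" tag is treated as AMBER mdout (which
    then requires ``sampling_interval``); anything else as tabular CSV.
    An explicit ``dialect`` ("amber_mdout" or "tabular_csv") overrides
    detection.
    """
    if dialect is None:
        head = Path(path).read_text()[:65536]
        dialect = "amber_mdout" if "DV/DL" in head else "tabular_csv"
    if dialect == "amber_mdout":
        if sampling_interval is None:
            raise ValueError("amber_mdout requires an explicit sampling_interval")
        return read_series_mdout(path, lambda_value, sampling_interval)
    if dialect == "tabular_csv":
        return read_series_csv(path, lambda_value, sampling_interval)
    raise ValueError(f"unknown dialect {dialect!r}; valid: amber_mdout, tabular_csv")


def write_series_csv(series: GradientSeries, path: str | Path) -> None:
    """Write the generic two-column (time_ns, dvdl_kcal_mol) format."""
    t = series.start_time + series.sampling_interval * np.arange(1, len(series) + 1)
    pd.DataFrame({"time_ns": t, "dvdl_kcal_mol": series.values}).to_csv(path, index=False)


def _canonical(obj: Any) -> Any:
    """Recursively replace NaN with None for canonical JSON."""
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_record(record: Any, path: str | Path) -> None:
    """Serialize a record to canonical JSON (sorted keys, repr floats).

    Accepts anything with ``to_dict()`` or a plain mapping; identical
    inputs produce byte-identical files.
    """
    data = record.to_dict() if hasattr(record, "to_dict") else record
    text = json.dumps(_canonical(data), sort_keys=True, indent=1, allow_nan=False)
    Path(path).write_text(text + "\n")


def read_record(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_protocol_config(path: str | Path) -> ProtocolConfig:
    """Load a protocol from a YAML mapping.

    Recognized keys: protocol (name), initial_ns, additional_ns,
    n_windows, js_threshold, min_decorrelated, soft_cap_ns,
    hard_cap_ns, n_bins. A named preset supplies defaults which
    explicit keys then override.
    """
    from .core import protocol_preset

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    base = protocol_preset(raw["protocol"]) if "protocol" in raw else None
    mapping = {
        "initial_ns": "initial_length",
        "additional_ns": "additional_length",
        "n_windows": "n_windows",
        "js_threshold": "js_threshold",
        "min_decorrelated": "min_decorrelated",
        "soft_cap_ns": "soft_cap",
        "hard_cap_ns": "hard_cap",
        "n_bins": "n_bins",
    }
    kwargs = {
        "name": base.name if base else raw.get("protocol", "custom"),
        "initial_length": base.initial_length if base else None,
        "additional_length": base.additional_length if base else None,
        "n_windows": base.n_windows if base else 9,
        "js_threshold": base.js_threshold if base else 0.1,
        "min_decorrelated": base.min_decorrelated if base else 50,
        "soft_cap": base.soft_cap if base else 6.5,
        "hard_cap": base.hard_cap if base else 10.5,
        "n_bins": base.n_bins if base else 7,
    }
    for key, field in mapping.items():
        if key in raw:
            kwargs[field] = raw[key]
    if kwargs["initial_length"] is None or kwargs["additional_length"] is None:
        raise ValueError(f"{path}: initial_ns and additional_ns required without a preset")
    return ProtocolConfig(**kwargs)
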