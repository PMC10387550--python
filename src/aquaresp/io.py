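"""Delimited-text readers and writers for traces, events and setup configs.

Formats
-------
Animal trace: columns ``time,o2,temperature[,phase]``; comma or tab
delimited (auto-detected); ``#`` comment lines ignored.  Time is seconds by
default; declare ``time_unit: min`` in the config (or pass it explicitly)
for minute-stamped files — units are never guessed from the data.

Mito trace: columns ``time,o2_conc[,fluorescence]``.

Event sidecar: columns ``time,reagent,concentration,unit``.

Config: YAML with chamber volumes, fish mass, temperature, salinity,
barometric pressure and column units.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .traces import (
    MitoTrace,
    OxygenTrace,
    RespirometrySetup,
    TitrationEvent,
    TraceSchemaError,
)

__all__ = [
    "read_oxygen_trace",
    "write_oxygen_trace",
    "read_mito_trace",
    "write_mito_trace",
    "read_events",
    "write_events",
    "read_setup",
    "write_setup",
]

PathLike = Union[str, Path]

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "minutes": 60.0}


def _read_table(path: PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    if not lines:
        raise TraceSchemaError(f"{path}: empty file")
    sep = "\t" if "\t" in lines[0] else ","
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas detail
        raise TraceSchemaError(f"{path}: unparseable table ({exc})") from exc
    df.columns = [str(c).strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise TraceSchemaError(f"{path}: missing required column {col!r}")
    return df

def _numeric(df: pd.DataFrame, col: str, path: PathLike) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise TraceSchemaError(
            f"{path}: unparseable number in column {col!r} at line {bad[0] + 2}"
        )
    if vals.isna().any():
        raise TraceSchemaError(f"{path}: missing value in column {col!r}")
    return vals.to_numpy(dtype=float)


def read_oxygen_trace(
    path: PathLike,
    temperature: Optional[float] = None,
    time_unit: str = "s",
    chamber_id: Optional[str] = None,
) -> OxygenTrace:
    """Read a whole-animal O2 trace from delimited text.

    ``temperature`` overrides (or supplies, when the file lacks a
    temperature column) the record temperature.
    """
    if time_unit not in _TIME_FACTORS:
        raise TraceSchemaError(f"unknown time unit {time_unit!r}")
    df = _read_table(path, ("time", "o2"))
    t = _numeric(df, "time", path) * _TIME_FACTORS[time_unit]
    o2 = _numeric(df, "o2", path)
    if temperature is None:
        if "temperature" not in df.columns:
            raise TraceSchemaError(f"{path}: no temperature column and none supplied")
        temperature = float(_numeric(df, "temperature", path).mean())
    phase = (
        df["phase"].astype(str).str.strip().to_numpy()
        if "phase" in df.columns
        else np.full(len(t), "measure", dtype=object)
    )
    if np.any(np.diff(t) <= 0):
        raise TraceSchemaError(f"{path}: time not strictly increasing")
    return OxygenTrace(t, o2, temperature, phase, chamber_id or Path(path).stem)


def write_oxygen_trace(trace: OxygenTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "time": trace.time,
            "o2": trace.o2,
            "temperature": np.full(len(trace.time), trace.temperature),
            "phase": trace.phase,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_mito_trace(
    path: PathLike,
    events: Optional[PathLike] = None,
    temperature: float = 21.0,
    time_unit: str = "s",
) -> MitoTrace:
    """Read an O2k-style trace (and optional titration-event sidecar)."""
    if time_unit not in _TIME_FACTORS:
        raise TraceSchemaError(f"unknown time unit {time_unit!r}")
    df = _read_table(path, ("time", "o2_conc"))
    t = _numeric(df, "time", path) * _TIME_FACTORS[time_unit]
    o2 = _numeric(df, "o2_conc", path)
    fluor = _numeric(df, "fluorescence", path) if "fluorescence" in df.columns else None
    ev = read_events(events) if events is not None else []
    return MitoTrace(t, o2, ev, fluor, temperature)


def write_mito_trace(trace: MitoTrace, path: PathLike, events: Optional[PathLike] = None) -> None:
    cols = {"time": trace.time, "o2_conc": trace.o2_conc}
    if trace.fluorescence is not None:
        cols["fluorescence"] = trace.fluorescence
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    if events is not None:
        write_events(trace.events, events)


def read_events(path: PathLike) -> list[TitrationEvent]:
    df = _read_table(path, ("time", "reagent", "concentration"))
    unit = df["unit"] if "unit" in df.columns else pd.Series(["mM"] * len(df))
    out = []
    for i in range(len(df)):
        out.append(
            TitrationEvent(
                float(df["time"].iloc[i]),
                str(df["reagent"].iloc[i]).strip(),
                float(df["concentration"].iloc[i]),
                str(unit.iloc[i]).strip(),
            )
        )
    return out


def write_events(events, path: PathLike) -> None:
    pd.DataFrame(
        {
            "time": [e.time for e in events],
            "reagent": [e.reagent for e in events],
            "concentration": [e.concentration for e in events],
            "unit": [e.unit for e in events],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_setup(path: PathLike) -> RespirometrySetup:
    """Read a respirometry setup config (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text())
    return RespirometrySetup(
        vr_l=float(cfg["vr_l"]),
        mb_kg=float(cfg["mb_kg"]),
        temperature=float(cfg["temperature"]),
        salinity=float(cfg.get("salinity", 35.0)),
        barometric_pressure=float(cfg.get("barometric_pressure", 101.325)),
        vf_l=None if cfg.get("vf_l") is None else float(cfg["vf_l"]),
    )


def write_setup(setup: RespirometrySetup, path: PathLike) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "vr_l": setup.vr_l,
                "mb_kg": setup.mb_kg,
                "temperature": setup.temperature,
                "salinity": setup.salinity,
                "barometric_pressure": setup.barometric_pressure,
                "vf_l": setup.vf_l,
            },
            sort_keys=False,
        )
    )
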