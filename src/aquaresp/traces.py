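"""Core data model: oxygen traces, respirometer setup, mitochondrial traces.

Containers are thin dataclasses over numpy arrays; validation happens at
construction so downstream analysis can assume clean inputs (strictly
increasing time, non-negative oxygen, contiguous phase runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PHASES",
    "MITO_REAGENTS",
    "TraceSchemaError",
    "VocabularyError",
    "ProtocolOrderError",
    "ConfigurationError",
    "InsufficientDataError",
    "OxygenTrace",
    "RespirometrySetup",
    "TitrationEvent",
    "MitoTrace",
]

#: Valid phase labels for whole-animal traces.
PHASES = ("flush", "wait", "measure", "closed_hypoxia", "recovery")

#: Reagent vocabulary for the mitochondrial titration protocol.
MITO_REAGENTS = (
    "pyruvate",
    "malate",
    "ADP",
    "succinate",
    "H2O2",
    "catalase",
    "oligomycin",
    "CCCP",
    "antimycin_a",
    "ascorbate",
    "TMPD",
    "azide",
)


class TraceSchemaError(ValueError):
    """A trace file or array set violates the expected schema."""


class VocabularyError(ValueError):
    """An event names a reagent outside the protocol vocabulary."""


class ProtocolOrderError(ValueError):
    """Titration events violate the expected assay ordering."""


class ConfigurationError(ValueError):
    """Physically impossible setup (e.g. chamber smaller than the fish)."""


class InsufficientDataError(ValueError):
    """Not enough data to perform the requested estimate."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceSchemaError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise TraceSchemaError(f"{name} contains non-finite values")
    return arr


@dataclass
class OxygenTrace:
    """Timestamped dissolved-oxygen record from one respirometer chamber.

    Attributes
    ----------
    time : array, seconds from record start, strictly increasing.
    o2 : array, % air saturation (>= 0; values > 100 tolerated and flagged
        as supersaturation).
    temperature : float, water temperature in degC for the whole record.
    phase : array of str, one label per sample from :data:`PHASES`.
    chamber_id : str identifier.
    """

    time: np.ndarray
    o2: np.ndarray
    temperature: float
    phase: np.ndarray
    chamber_id: str = "chamber-1"

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.o2 = _as_float_array(self.o2, "o2")
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.o2) == len(self.phase)):
            raise TraceSchemaError("time, o2 and phase must have equal length")
        if len(self.time) == 0:
            raise TraceSchemaError("empty trace")
        if np.any(np.diff(self.time) <= 0):
            raise TraceSchemaError("time must be strictly increasing")
        if np.any(self.o2 < 0):
            raise TraceSchemaError("o2 (% air saturation) must be >= 0")
        bad = set(self.phase) - set(PHASES)
        if bad:
            raise TraceSchemaError(f"unknown phase labels: {sorted(bad)}")

    @property
    def supersaturated(self) -> bool:
        """True when any sample exceeds 100% air saturation."""
        return bool(np.any(self.o2 > 100.0))

    def phase_runs(self) -> list[tuple[str, int, int]]:
        """Contiguous phase runs as (label, start_index, stop_index) slices."""
        runs = []
        start = 0
        for i in range(1, len(self.phase) + 1):
            if i == len(self.phase) or self.phase[i] != self.phase[start]:
                runs.append((str(self.phase[start]), start, i))
                start = i
        return runs

    def subset(self, start: int, stop: int) -> "OxygenTrace":
        return OxygenTrace(
            self.time[start:stop],
            self.o2[start:stop],
            self.temperature,
            self.phase[start:stop],
            self.chamber_id,
        )


@dataclass
class RespirometrySetup:
    """Physical configuration of one intermittent-flow respirometry run.

    ``vf_l`` defaults to the body mass expressed in litres (1 g of fish
    displaces 1 mL of water); pass an explicit value to override.
    """

    vr_l: float  # respirometer volume incl. tubing, L
    mb_kg: float  # fish body mass, kg
    temperature: float  # degC
    salinity: float = 35.0  # ppt
    barometric_pressure: float = 101.325  # kPa
    vf_l: Optional[float] = None  # fish volume, L

    def __post_init__(self) -> None:
        if self.mb_kg <= 0:
            raise ConfigurationError("fish mass must be > 0")
        if self.vf_l is None:
            self.vf_l = float(self.mb_kg)  # 1 g == 1 mL
        if self.vf_l <= 0:
            raise ConfigurationError("fish volume must be > 0")
        if self.vr_l <= self.vf_l:
            raise ConfigurationError(
                f"chamber volume {self.vr_l} L must exceed fish volume {self.vf_l} L"
            )

    @property
    def alpha(self) -> float:
        """O2 solubility, mg O2 per litre per % air saturation."""
        from .units import o2_solubility

        return o2_solubility(self.temperature, self.salinity) / 100.0


@dataclass(frozen=True)
class TitrationEvent:
    """One reagent addition in a mitochondrial assay."""

    time: float  # seconds
    reagent: str
    concentration: float  # final chamber concentration
    unit: str = "mM"

    def __post_init__(self) -> None:
        if self.reagent not in MITO_REAGENTS:
            raise VocabularyError(
                f"unknown reagent {self.reagent!r}; expected one of {MITO_REAGENTS}"
            )


@dataclass
class MitoTrace:
    """High-resolution respirometer (O2k-style) record.

    ``fluorescence`` is the calibrated safranin concentration in the bath
    (uM); None when the potentiometric dye channel was not run.
    """

    time: np.ndarray  # seconds
    o2_conc: np.ndarray  # uM (nmol/mL)
    events: Sequence[TitrationEvent] = field(default_factory=list)
    fluorescence: Optional[np.ndarray] = None
    temperature: float = 21.0  # degC

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.o2_conc = _as_float_array(self.o2_conc, "o2_conc")
        if len(self.time) != len(self.o2_conc):
            raise TraceSchemaError("time and o2_conc must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise TraceSchemaError("time must be strictly increasing")
        if np.any(self.o2_conc < 0):
            raise TraceSchemaError("o2_conc must be >= 0")
        if self.fluorescence is not None:
            self.fluorescence = _as_float_array(self.fluorescence, "fluorescence")
            if len(self.fluorescence) != len(self.time):
                raise TraceSchemaError("fluorescence length mismatch")
            if np.any(self.fluorescence < 0):
                raise TraceSchemaError("fluorescence must be >= 0")
        self.events = sorted(self.events, key=lambda e: e.time)

    def event_times(self, reagent: str) -> list[float]:
        return [e.time for e in self.events if e.reagent == reagent]
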