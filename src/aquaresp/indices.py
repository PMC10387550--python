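"""Morphometric and haematological indices plus group summarisation.

Derived per-fish indices (condition factor, relative organ mass, mean
corpuscular haemoglobin) are computed per individual and then averaged;
the ratio-of-group-means variant is available through
:func:`percent_change_summary` for reporting average treatment effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .traces import InsufficientDataError

__all__ = [
    "TREATMENTS",
    "FishRecord",
    "condition_factor",
    "relative_organ_mass",
    "mch",
    "group_summary",
    "percent_change_summary",
]

#: Experimental groups: control at the start, 1/10/30 days of warming, and a
#: second control held to the end of the experiment.
TREATMENTS = ("control_start", "d1_25C", "d10_25C", "d30_25C", "control_end")


@dataclass
class FishRecord:
    """Per-fish morphometric / blood record."""

    mb_kg: float
    fork_length_m: float
    treatment: str
    ventricle_mass_kg: Optional[float] = None
    spleen_mass_kg: Optional[float] = None
    liver_mass_kg: Optional[float] = None
    hct_pct: Optional[float] = None
    hb_g_l: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mb_kg <= 0 or self.fork_length_m <= 0:
            raise ValueError("mass and fork length must be > 0")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.hct_pct is not None and not (0 < self.hct_pct < 100):
            raise ValueError("haematocrit must be in (0, 100)%")


def condition_factor(mb_kg: float, fl_m: float) -> float:
    """Condition factor K = Mb / FL^3 * 100, in kg and m.

    Note these are literal SI units (not the conventional g/cm Fulton's K);
    pass gram/centimetre inputs for the conventional scale.
    """
    if mb_kg <= 0 or fl_m <= 0:
        raise ValueError("mass and length must be > 0")
    return mb_kg / fl_m**3 * 100.0


def relative_organ_mass(m_organ_kg: float, mb_kg: float) -> float:
    """Organ wet mass as a percentage of body mass."""
    if not (0 < m_organ_kg < mb_kg):
        raise ValueError("organ mass must be positive and below body mass")
    return m_organ_kg / mb_kg * 100.0


def mch(hb_g_l: float, hct_pct: float) -> float:
    """Mean corpuscular haemoglobin concentration, g/L of packed cells.

    MCH = Hb / HCT * 100 with Hb in g/L and HCT in %.
    """
    if hb_g_l <= 0:
        raise ValueError("haemoglobin must be > 0")
    if not (0 < hct_pct < 100):
        raise ValueError("haematocrit must be in (0, 100)%")
    return hb_g_l / hct_pct * 100.0


def group_summary(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
    by: str = "treatment",
    metric: Optional[str] = None,
) -> pd.DataFrame:
    """Mean, standard error and n per group.

    Accepts either a mapping {group: values} or a long-format DataFrame
    with a grouping column ``by`` and a value column ``metric``.  SE is
    sd/sqrt(n) with the sample (ddof=1) standard deviation; singleton
    groups get NaN SE and are flagged.
    """
    if isinstance(values, pd.DataFrame):
        if metric is None:
            raise ValueError("metric column name required for DataFrame input")
        grouped = {k: g[metric].to_numpy(dtype=float) for k, g in values.groupby(by)}
    else:
        grouped = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    rows = []
    for group, v in grouped.items():
        n = len(v)
        if n == 0:
            raise InsufficientDataError(f"group {group!r} is empty")
        se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "group": group,
                "mean": float(v.mean()),
                "se": se,
                "n": n,
                "singleton": n < 2,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def percent_change_summary(
    control_mean: float,
    treatment_means: Iterable[float],
    round_to_int: bool = True,
) -> float:
    """Average percent change of treatment means relative to a control mean.

    100 * (mean(treatments)/control - 1), rounded to the nearest integer
    percent for reporting by default.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    tm = np.asarray(list(treatment_means), dtype=float)
    pct = 100.0 * (tm.mean() / control_mean - 1.0)
    return float(round(pct)) if round_to_int else float(pct)
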