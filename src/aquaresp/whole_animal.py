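"""Whole-animal metabolic rates from intermittent-flow respirometry.

An intermittent-flow run cycles flush / wait / measure phases.  During each
sealed ``measure`` phase oxygen declines linearly while the fish respires;
the per-cycle OLS slope (% air saturation per hour), corrected for
background (bacterial) respiration, converts to a mass-specific oxygen
uptake rate

    MO2 = (Vr - Vf) * |dSat/dt| * alpha / Mb    [mg O2 kg-1 h-1]

where Vr and Vf are chamber and fish volume (L), alpha the O2 solubility
per % saturation and Mb body mass (kg).  From the resulting MO2 series the
headline metrics follow: SMR (mean of the 10 lowest accepted values), MMR
(highest value, normally the first cycle after an exhaustive chase),
aerobic scope MS = MMR - SMR, and the Q10 temperature coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .traces import InsufficientDataError, OxygenTrace, RespirometrySetup

__all__ = [
    "CycleMeasurement",
    "MO2Entry",
    "MO2Series",
    "MetabolicSummary",
    "extract_cycle_slopes",
    "background_correct",
    "compute_mo2",
    "mo2_series",
    "estimate_smr",
    "estimate_mmr",
    "aerobic_scope",
    "q10",
    "flag_outliers",
]


@dataclass
class CycleMeasurement:
    """OLS slope of one sealed measure cycle."""

    t_start: float  # s
    t_end: float  # s
    slope: float  # delta %sat per hour (negative while the fish respires)
    r2: float  # nan when undefined (flat line)
    n_points: int
    quality_ok: bool = True
    background_subtracted: float = 0.0  # %sat/h removed by correction
    flagged_reason: str = ""

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class MO2Entry:
    t_mid: float  # s
    mo2: float  # mg O2 kg-1 h-1
    background_corrected: bool
    quality_ok: bool


@dataclass
class MO2Series:
    """Per-cycle mass-specific oxygen uptake over time."""

    entries: list[MO2Entry] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.t_mid for e in self.entries])

    @property
    def values(self) -> np.ndarray:
        return np.array([e.mo2 for e in self.entries])

    @property
    def quality(self) -> np.ndarray:
        return np.array([e.quality_ok for e in self.entries], dtype=bool)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MetabolicSummary:
    smr: float
    mmr: float
    ms: float
    smr_n_used: int
    q10_vs_reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mmr < self.smr:
            raise ValueError("MMR must be >= SMR")


def _ols_slope(t_h: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope (per hour) and R^2 of y on t; R^2 is nan for a flat response."""
    slope, _ = np.polyfit(t_h, y, 1)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(slope), float("nan")
    resid = y - np.polyval(np.polyfit(t_h, y, 1), t_h)
    return float(slope), float(1.0 - np.sum(resid**2) / ss_tot)


def extract_cycle_slopes(
    trace: OxygenTrace,
    settle_s: float = 30.0,
    r2_threshold: float = 0.90,
) -> list[CycleMeasurement]:
    """One OLS slope per contiguous ``measure`` run.

    The first ``settle_s`` seconds of each run are discarded (mixing
    settle window).  Cycles with R^2 below ``r2_threshold`` — or with an
    undefined R^2 (flat trace) — are flagged, not dropped.
    """
    cycles = []
    for label, start, stop in trace.phase_runs():
        if label != "measure":
            continue
        t = trace.time[start:stop]
        y = trace.o2[start:stop]
        keep = t >= t[0] + settle_s
        t, y = t[keep], y[keep]
        if len(t) < 3:
            continue
        slope, r2 = _ols_slope(t / 3600.0, y)
        ok = bool(np.isfinite(r2) and r2 >= r2_threshold)
        reason = "" if ok else ("r2 undefined" if not np.isfinite(r2) else "low r2")
        cycles.append(
            CycleMeasurement(float(t[0]), float(t[-1]), slope, r2, len(t), ok, 0.0, reason)
        )
    if not cycles:
        raise InsufficientDataError("trace contains no usable measure phase")
    return cycles


def background_correct(
    cycles: Sequence[CycleMeasurement],
    pre_rate: float,
    post_rate: float,
    t_pre: float,
    t_post: float,
) -> list[CycleMeasurement]:
    """Subtract linearly time-interpolated background respiration.

    ``pre_rate`` / ``post_rate`` are mean empty-chamber slopes (%sat/h,
    negative for consumption) measured at times ``t_pre`` and ``t_post``.
    Background is assumed to grow linearly between them; each cycle's
    midpoint picks its interpolated background slope, which is subtracted.
    A cycle whose background exceeds the whole fish slope (corrected slope
    positive) is flagged as implausible.
    """
    if t_post <= t_pre:
        raise ValueError("t_post must exceed t_pre")
    out = []
    for c in cycles:
        frac = np.clip((c.t_mid - t_pre) / (t_post - t_pre), 0.0, 1.0)
        bg = pre_rate + (post_rate - pre_rate) * frac
        corrected = c.slope - bg
        ok = c.quality_ok
        reason = c.flagged_reason
        if corrected > 0 and c.slope < 0:
            ok = False
            reason = (reason + "; " if reason else "") + "background exceeds fish slope"
        out.append(
            CycleMeasurement(
                c.t_start, c.t_end, corrected, c.r2, c.n_points, ok, float(bg), reason
            )
        )
    return out


def compute_mo2(cycle: CycleMeasurement, setup: RespirometrySetup) -> float:
    """Mass-specific oxygen uptake for one cycle, mg O2 kg-1 h-1.

    Respiration (negative slope) yields positive MO2; a positive
    (implausible) corrected slope yields a negative MO2 which the series
    builder flags rather than drops.
    """
    return (setup.vr_l - setup.vf_l) * (-cycle.slope) * setup.alpha / setup.mb_kg


def mo2_series(
    cycles: Sequence[CycleMeasurement],
    setup: RespirometrySetup,
    background_corrected: bool = True,
) -> MO2Series:
    entries = []
    for c in cycles:
        v = compute_mo2(c, setup)
        ok = c.quality_ok and v >= 0
        entries.append(MO2Entry(c.t_mid, v, background_corrected, ok))
    return MO2Series(entries)


def estimate_smr(
    series: MO2Series,
    window: Optional[tuple[float, float]] = None,
    n_lowest: int = 10,
    outlier_k_sd: Optional[float] = 2.0,
) -> tuple[float, int]:
    """SMR as the mean of the ``n_lowest`` lowest accepted MO2 values.

    ``window`` restricts the candidate cycles (seconds, inclusive); use it
    to exclude the closed hypoxia drawdown and the post-chase recovery so
    oxyconforming or elevated values cannot deflate/inflate the estimate.
    Outlier flagging (|z| > ``outlier_k_sd``) is applied to the candidate
    low set before averaging so one artifactual near-zero cycle cannot
    dominate.  Returns (smr, n_used).
    """
    t, v, q = series.times, series.values, series.quality
    mask = q.copy()
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    vals = v[mask]
    if len(vals) == 0:
        raise InsufficientDataError("no accepted MO2 values in SMR window")
    if len(vals) < n_lowest:
        import warnings

        warnings.warn(
            f"only {len(vals)} accepted values available for SMR (wanted {n_lowest})",
            stacklevel=2,
        )
    # stable ordering: by value then time — deterministic tie-breaking
    order = np.lexsort((t[mask], vals))
    low = vals[order][:n_lowest]
    if outlier_k_sd is not None and len(low) >= 3:
        low = low[~flag_outliers(low, outlier_k_sd)]
    return float(np.mean(low)), int(len(low))


def estimate_mmr(series: MO2Series) -> tuple[float, float]:
    """Maximum accepted MO2 and its timestamp."""
    v, q, t = series.values, series.quality, series.times
    if not np.any(q):
        raise InsufficientDataError("no accepted MO2 values")
    i = int(np.argmax(np.where(q, v, -np.inf)))
    return float(v[i]), float(t[i])


def aerobic_scope(smr: float, mmr: float) -> float:
    """Aerobic metabolic scope MS = MMR - SMR."""
    if mmr < smr:
        raise ValueError(f"MMR ({mmr}) must be >= SMR ({smr})")
    return mmr - smr


def q10(rate_ref: float, rate_test: float, t_ref: float, t_test: float) -> float:
    """Temperature coefficient Q10 = (rate_test/rate_ref)^(10/(t_test-t_ref))."""
    if rate_ref <= 0 or rate_test <= 0:
        raise ValueError("rates must be > 0")
    if t_test == t_ref:
        raise ValueError("temperatures must differ")
    return float((rate_test / rate_ref) ** (10.0 / (t_test - t_ref)))


def flag_outliers(values, k_sd: float = 2.0) -> np.ndarray:
    """Mask values farther than ``k_sd`` standard deviations from the mean.

    Each value is scored against the mean and SD of the *other* values
    (leave-one-out), since a gross outlier inflates the plain sample SD
    enough to mask itself in small samples.  Removal is the caller's
    choice; all-equal input flags nothing.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise InsufficientDataError("need at least 3 values for outlier flagging")
    s, q = v.sum(), np.sum(v * v)
    loo_mean = (s - v) / (n - 1)
    loo_var = (q - v * v - (n - 1) * loo_mean**2) / (n - 2)
    loo_sd = np.sqrt(np.clip(loo_var, 0.0, None))
    dev = np.abs(v - loo_mean)
    return np.where(loo_sd > 0, dev > k_sd * loo_sd, dev > 0)
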