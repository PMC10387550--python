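"""Hypoxia tolerance: Pcrit, PLOE and the post-hypoxia oxygen debt (EPOC).

During a closed drawdown the fish first oxyregulates (holds MO2 near SMR)
and then, below the critical oxygen pressure Pcrit, oxyconforms: MO2 falls
with ambient PO2.  Pcrit is estimated with the SMR-intercept method — an
ordinary least-squares regression through the sub-SMR (oxyconforming)
points, intersected with the SMR level.  PLOE is the PO2 at the operator-
annotated moment of loss of equilibrium; it is a lookup with interpolation,
not a detector, because LOE is a behavioural observation.

EPOC quantifies the oxygen debt repaid after re-oxygenation: the recovery
baseline is SMR + 10% (fish rarely settle all the way back to SMR), and
the debt is the trapezoidal area of MO2 above that threshold up to the
first sustained downward crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .traces import InsufficientDataError, OxygenTrace, RespirometrySetup
from .units import percent_sat_to_po2
from .whole_animal import MO2Series, _ols_slope

__all__ = [
    "HypoxiaResult",
    "EpocResult",
    "drawdown_series",
    "detect_pcrit",
    "detect_ploe",
    "epoc_metrics",
]


@dataclass
class HypoxiaResult:
    pcrit: float  # kPa
    regression_slope: float  # MO2 per kPa (positive)
    regression_intercept: float  # MO2 at PO2 = 0
    n_conforming_points: int
    smr_used: float
    ploe: Optional[float] = None  # kPa

    def __post_init__(self) -> None:
        if self.ploe is not None and not self.pcrit > self.ploe:
            raise ValueError("Pcrit must exceed PLOE")


@dataclass
class EpocResult:
    peak_mo2: float  # mg O2 kg-1 h-1
    total_debt: float  # mg O2 kg-1
    recovery_time: float  # h
    debt_per_hour: float  # mg O2 kg-1 h-1
    threshold: float  # = 1.10 * SMR
    never_exceeded: bool = False
    right_censored: bool = False
    clipped_fraction: float = 0.0  # |negative area| / total, flag if > 5%


def drawdown_series(
    trace: OxygenTrace,
    setup: RespirometrySetup,
    phase: str = "closed_hypoxia",
    bin_s: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval (PO2 kPa, MO2) points from a closed drawdown.

    With ``bin_s=None`` MO2 is the two-point slope of each consecutive
    sample pair, paired with the PO2 at the interval midpoint oxygen
    level — exact on noise-free data.  With ``bin_s`` set, samples are
    grouped into consecutive ``bin_s``-second windows and each bin
    contributes one OLS slope paired with its mean oxygen level, which is
    what noisy raw traces need.
    """
    sel = np.asarray([p == phase for p in trace.phase], dtype=bool)
    if sel.sum() < 3:
        raise InsufficientDataError(f"no {phase!r} phase in trace")
    t = trace.time[sel] / 3600.0  # h
    o2 = trace.o2[sel]
    if bin_s is None:
        slopes = np.diff(o2) / np.diff(t)  # %sat / h
        mid_sat = 0.5 * (o2[:-1] + o2[1:])
    else:
        bins = np.floor((trace.time[sel] - trace.time[sel][0]) / bin_s).astype(int)
        slopes_l, sat_l = [], []
        for b in np.unique(bins):
            in_bin = bins == b
            if in_bin.sum() < 3:
                continue
            slope, _ = np.polyfit(t[in_bin], o2[in_bin], 1)
            slopes_l.append(slope)
            sat_l.append(o2[in_bin].mean())
        slopes, mid_sat = np.asarray(slopes_l), np.asarray(sat_l)
    mo2 = (setup.vr_l - setup.vf_l) * (-slopes) * setup.alpha / setup.mb_kg
    po2 = percent_sat_to_po2(mid_sat, setup.temperature, setup.barometric_pressure)
    return po2, mo2


def detect_pcrit(
    po2: np.ndarray,
    mo2: np.ndarray,
    smr: float,
    contiguous_suffix: bool = True,
    smr_margin: float = 0.05,
) -> HypoxiaResult:
    """SMR-intercept Pcrit from a drawdown MO2-vs-PO2 series.

    The points entering the regression are, by default, the maximal
    contiguous run at the low-PO2 end of the drawdown whose MO2 sits
    clearly below SMR — below ``(1 - smr_margin) * smr`` — so that
    regulating-plateau scatter hovering just under a slightly
    over-estimated SMR cannot flood the oxyconforming regression
    (spurious sub-SMR dips at high PO2 are likewise excluded by the
    contiguity rule; set ``contiguous_suffix=False`` to use all sub-SMR
    points instead).  Pcrit is the PO2 where the OLS line
    MO2 = a + b*PO2 equals SMR.
    """
    po2 = np.asarray(po2, dtype=float)
    mo2 = np.asarray(mo2, dtype=float)
    order = np.argsort(po2)[::-1]  # high -> low PO2
    p, m = po2[order], mo2[order]
    sub = m < smr * (1.0 - smr_margin)
    if contiguous_suffix:
        # longest run of sub-SMR points reaching the lowest-PO2 end
        idx = np.where(~sub)[0]
        start = (idx[-1] + 1) if len(idx) else 0
        keep = np.zeros(len(p), dtype=bool)
        keep[start:] = True
    else:
        keep = sub
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} sub-SMR points; need >= 3 for the "
            "oxyconforming regression"
        )
    slope, intercept = np.polyfit(p[keep], m[keep], 1)
    if slope <= 0:
        raise ValueError(
            "degenerate oxyconforming fit: non-positive slope of MO2 on PO2"
        )
    pcrit = (smr - intercept) / slope
    return HypoxiaResult(
        pcrit=float(pcrit),
        regression_slope=float(slope),
        regression_intercept=float(intercept),
        n_conforming_points=int(keep.sum()),
        smr_used=float(smr),
    )


def detect_ploe(
    trace: OxygenTrace,
    loe_time: float,
    barometric_pressure: Optional[float] = None,
) -> float:
    """PO2 (kPa) at the annotated loss-of-equilibrium time.

    Linear interpolation between the bracketing trace samples; an
    annotation exactly at a sample returns that sample's PO2.
    """
    if not (trace.time[0] <= loe_time <= trace.time[-1]):
        raise ValueError(
            f"LOE time {loe_time}s outside trace range "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    sat = float(np.interp(loe_time, trace.time, trace.o2))
    pbar = 101.325 if barometric_pressure is None else barometric_pressure
    return percent_sat_to_po2(sat, trace.temperature, pbar)


def epoc_metrics(
    times_h: np.ndarray,
    mo2: np.ndarray,
    smr: float,
    sustained_cycles: int = 2,
    clip_negative: bool = True,
) -> EpocResult:
    """Oxygen-debt parameters from a post-hypoxia recovery MO2 series.

    threshold = 1.1 * SMR.  Recovery time is the first downward crossing
    of the threshold sustained for ``sustained_cycles`` consecutive cycles
    (linear interpolation between the bracketing points).  Total debt is
    the trapezoidal area of (MO2 - threshold) over [start, recovery],
    negative excursions clipped at zero (flagged when the clipped area
    exceeds 5% of the total).  Never-exceeding series return an all-zero
    flagged result; series that never recross are right-censored with the
    debt integrated to the last sample.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(mo2, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("recovery series needs >= 2 points")
    thr = 1.10 * smr
    peak = float(np.max(v))
    if peak <= thr:
        return EpocResult(peak, 0.0, 0.0, 0.0, thr, never_exceeded=True)

    excess = v - thr
    # first sustained downward crossing after the series has been above
    t_rec = None
    above_seen = False
    for i in range(len(v)):
        if excess[i] > 0:
            above_seen = True
            continue
        if not above_seen:
            continue
        if all(excess[j] <= 0 for j in range(i, min(i + sustained_cycles, len(v)))) and (
            i + sustained_cycles <= len(v)
        ):
            # interpolate the crossing between i-1 and i
            e0, e1 = excess[i - 1], excess[i]
            frac = e0 / (e0 - e1) if e0 != e1 else 0.0
            t_rec = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    censored = t_rec is None
    t_end = t[-1] if censored else t_rec

    # integrate clipped excess on [t[0], t_end], inserting the crossing point
    tt = t[t <= t_end]
    vv = excess[: len(tt)]
    if not censored and (len(tt) == 0 or tt[-1] < t_end):
        tt = np.append(tt, t_end)
        vv = np.append(vv, 0.0)
    raw = np.trapezoid(vv, tt)
    clipped = np.trapezoid(np.clip(vv, 0.0, None), tt)
    area = float(clipped if clip_negative else raw)
    clip_frac = float((clipped - raw) / clipped) if clipped > 0 else 0.0
    rec_time = float(t_end - t[0])
    return EpocResult(
        peak_mo2=peak,
        total_debt=area,
        recovery_time=rec_time,
        debt_per_hour=area / rec_time if rec_time > 0 else 0.0,
        threshold=thr,
        right_censored=censored,
        clipped_fraction=clip_frac,
    )
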