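"""High-resolution mitochondrial respirometry: state fluxes, coupling,
oxygen kinetics and membrane potential.

A permeabilised-tissue assay titrates substrates, inhibitors and an
uncoupler in a fixed order (a SUIT protocol): pyruvate+malate (complex-I
leak), ADP (CI OXPHOS), succinate (CI+CII OXPHOS), a drawdown into brief
anoxia for the O2 kinetics, reoxygenation with H2O2/catalase, oligomycin
(CI+CII leak), CCCP (uncoupled electron-transport capacity), antimycin A
(residual non-mitochondrial consumption, ROX), ascorbate+TMPD (maximal
cytochrome-c-oxidase rate) and azide (TMPD auto-oxidation blank).

Oxygen flux is the negative time derivative of chamber O2 concentration,
scaled to tissue mass:

    JO2 = -d[O2]/dt * 1000 * V_chamber(mL) / m_tissue(mg)   [pmol s-1 mg-1]

Each state is summarised by a 2-minute average taken from a steady segment
before the next titration.  ROX is subtracted from every state except the
CCO pair, whose blank is azide.  Mitochondrial O2 affinity (P50) comes
from a Hill fit of flux against O2 during the drawdown, gated at R2 > 0.70.
Membrane potential is estimated from the distribution of the cationic dye
safranin between bath and matrix via the Nernst equation, with the matrix
volume taken as 19.8% of tissue volume (1 mg == 1 uL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .traces import (
    ConfigurationError,
    InsufficientDataError,
    MitoTrace,
    ProtocolOrderError,
)

__all__ = [
    "STATE_ORDER",
    "StateMeasure",
    "MitoStateTable",
    "P50Fit",
    "NernstParams",
    "jo2_series",
    "jo2_from_trace",
    "extract_states",
    "rox_correct",
    "rcr",
    "p50_segment",
    "fit_p50",
    "hill",
    "safr_in_from_mass_balance",
    "membrane_potential",
    "nernst_slope_mv",
    "mito_work",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1
FARADAY = 96485.340  # C mol-1
LN10 = 2.3026  # decadic conversion used in the potentiometric calculation

#: Advisory plausibility band for heart-preparation RCR (logged, never fatal).
RCR_ADVISORY_RANGE = (10.6, 21.6)

#: (state name, reagents that must all have been added to enter the state).
#: ``None`` marks the reoxygenation step, which is not a measured state.
STATE_ORDER: tuple[tuple[Optional[str], frozenset], ...] = (
    ("Leak_CI", frozenset({"pyruvate", "malate"})),
    ("OXPHOS_CI", frozenset({"ADP"})),
    ("OXPHOS_CI_CII", frozenset({"succinate"})),
    (None, frozenset({"H2O2", "catalase"})),
    ("Leak_CI_CII", frozenset({"oligomycin"})),
    ("ETS_uncoupled", frozenset({"CCCP"})),
    ("ROX", frozenset({"antimycin_a"})),
    ("CCO_raw", frozenset({"ascorbate", "TMPD"})),
    ("AZ_background", frozenset({"azide"})),
)


@dataclass
class StateMeasure:
    jo2: float  # pmol O2 s-1 mg-1
    dpsi: Optional[float] = None  # mV, <= 0 when energized
    n_samples: int = 0
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class MitoStateTable:
    """Per-state fluxes and membrane potentials, raw or ROX-subtracted."""

    states: dict[str, StateMeasure] = field(default_factory=dict)
    net: bool = False  # True after ROX subtraction
    cco_net: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def jo2(self, state: str) -> float:
        return self.states[state].jo2

    def dpsi(self, state: str) -> Optional[float]:
        return self.states[state].dpsi

    def work(self, state: str) -> Optional[float]:
        m = self.states[state]
        if m.dpsi is None:
            return None
        return mito_work(m.jo2, m.dpsi)

    def __contains__(self, state: str) -> bool:
        return state in self.states


@dataclass
class P50Fit:
    jmax: float  # pmol O2 s-1 mg-1
    p50: float
    hill_h: float
    r2: float
    unit: str = "uM"
    accepted: bool = True


@dataclass
class NernstParams:
    """Constants and geometry for the safranin membrane-potential estimate."""

    temperature_k: float
    chamber_volume_ml: float
    tissue_mass_mg: float
    mito_fraction: float = 0.198  # matrix volume fraction of heart tissue
    z: int = 1
    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if not self.temperature_k > 273.0:
            raise ValueError("temperature must be above 273 K")
        if not (0.0 < self.mito_fraction < 1.0):
            raise ValueError("mito_fraction must be in (0, 1)")

    @property
    def v_mito_ul(self) -> float:
        """Matrix volume, uL (tissue density 1 mg == 1 uL assumed)."""
        return self.tissue_mass_mg * self.mito_fraction

    @property
    def v_chamber_ul(self) -> float:
        return self.chamber_volume_ml * 1000.0


# ------------------------------------------------------------------ flux --

def jo2_series(
    trace: MitoTrace,
    tissue_mass_mg: float,
    chamber_volume_ml: float,
    smooth_s: float = 20.0,
    method: str = "savgol",
) -> np.ndarray:
    """Mass-specific O2 flux at every trace sample, pmol s-1 mg-1.

    ``savgol`` fits a local quadratic over ``smooth_s`` seconds (requires a
    uniform sample interval); ``central`` is the raw central difference.
    Positive d[O2]/dt (reoxygenation) yields negative JO2; callers should
    treat those samples as titration artifacts.
    """
    if tissue_mass_mg <= 0 or chamber_volume_ml <= 0:
        raise ConfigurationError("tissue mass and chamber volume must be > 0")
    t, c = trace.time, trace.o2_conc
    if method == "central":
        dcdt = np.gradient(c, t)
    elif method == "savgol":
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            dcdt = np.gradient(c, t)  # non-uniform: fall back
        else:
            win = max(5, int(round(smooth_s / dt[0])) | 1)  # odd
            if win > len(c):
                raise InsufficientDataError("trace shorter than smoothing kernel")
            dcdt = savgol_filter(c, win, polyorder=2, deriv=1, delta=dt[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return -dcdt * 1000.0 * chamber_volume_ml / tissue_mass_mg


def jo2_from_trace(
    trace: MitoTrace,
    window: tuple[float, float],
    tissue_mass_mg: float,
    chamber_volume_ml: float,
    smooth_s: float = 20.0,
) -> float:
    """Mean JO2 over a time window (seconds), pmol s-1 mg-1."""
    lo, hi = window
    if hi - lo < smooth_s:
        raise InsufficientDataError("window shorter than smoothing kernel")
    j = jo2_series(trace, tissue_mass_mg, chamber_volume_ml, smooth_s)
    sel = (trace.time >= lo) & (trace.time <= hi)
    if sel.sum() < 3:
        raise InsufficientDataError("window contains too few samples")
    return float(np.mean(j[sel]))


# ---------------------------------------------------------------- states --

def _stage_boundaries(trace: MitoTrace) -> list[tuple[Optional[str], float, float]]:
    """(state, start, end) windows from the titration events, order-checked."""
    stage = 0
    pending: set[str] = set()
    starts: list[tuple[Optional[str], float]] = []
    reagent_stage = {}
    for i, (_, reagents) in enumerate(STATE_ORDER):
        for r in reagents:
            reagent_stage[r] = i
    for ev in trace.events:
        if ev.reagent not in reagent_stage:
            continue
        s = reagent_stage[ev.reagent]
        if s < stage:
            raise ProtocolOrderError(
                f"reagent {ev.reagent!r} at t={ev.time}s arrives after stage "
                f"{STATE_ORDER[stage][0] or 'reoxygenation'} has begun"
            )
        stage = s
        pending.add(ev.reagent)
        if STATE_ORDER[s][1] <= pending:
            starts.append((STATE_ORDER[s][0], ev.time))
            pending = set()
    # close each window at the next event of any kind (or trace end)
    event_times = sorted(e.time for e in trace.events)
    out = []
    for name, t0 in starts:
        later = [t for t in event_times if t > t0]
        t1 = later[0] if later else float(trace.time[-1])
        out.append((name, t0, t1))
    return out


def _steady_window(
    t: np.ndarray,
    j: np.ndarray,
    t0: float,
    t1: float,
    avg_s: float = 120.0,
    end_buffer_s: float = 15.0,
    start_buffer_s: float = 15.0,
    cv_limit: float = 0.10,
) -> tuple[float, float, bool]:
    """Pick the 2-min averaging sub-window inside a state window.

    Preference: the last ``avg_s`` seconds ending ``end_buffer_s`` before
    the next titration, provided the flux CV there is below ``cv_limit``;
    otherwise the most stable ``avg_s`` sub-window by rolling CV.  Returns
    (lo, hi, flagged) — flagged when no sub-window met the CV rule or the
    state was too short for a full 2-min average.
    """
    lo_lim, hi_lim = t0 + start_buffer_s, t1 - end_buffer_s
    if hi_lim - lo_lim < avg_s:
        return lo_lim, hi_lim, True

    def cv(lo: float, hi: float) -> float:
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            return np.inf
        v = j[sel]
        m = v.mean()
        if m <= 0:
            return np.inf
        return float(v.std(ddof=1) / m)

    lo, hi = hi_lim - avg_s, hi_lim
    if cv(lo, hi) < cv_limit:
        return lo, hi, False
    # slide a 2-min window in 5-s steps, keep the most stable
    best, best_cv = (lo, hi), np.inf
    start = lo_lim
    while start + avg_s <= hi_lim + 1e-9:
        c = cv(start, start + avg_s)
        if c < best_cv:
            best, best_cv = (start, start + avg_s), c
        start += 5.0
    return best[0], best[1], not np.isfinite(best_cv)


def extract_states(
    trace: MitoTrace,
    tissue_mass_mg: float,
    chamber_volume_ml: float,
    total_safr_um: float = 2.0,
    mito_fraction: float = 0.198,
    smooth_s: float = 20.0,
    low_o2_um: float = 30.0,
) -> MitoStateTable:
    """Raw (not ROX-subtracted) per-state 2-min means of JO2 and dPsi.

    Partial protocols are allowed — missing states are simply absent from
    the table.  Out-of-order events raise :class:`ProtocolOrderError`.
    When the trace carries a calibrated safranin channel, the per-state
    bath dye concentration is converted to membrane potential through the
    matrix mass balance and the Nernst equation.

    A state window that runs into the anoxic drawdown (chamber O2 falling
    below ``low_o2_um``) is truncated at that crossing: flux there is
    O2-limited and belongs to the kinetics segment, not the state average.
    """
    j = jo2_series(trace, tissue_mass_mg, chamber_volume_ml, smooth_s)
    windows = _stage_boundaries(trace)
    params = NernstParams(
        temperature_k=trace.temperature + 273.15,
        chamber_volume_ml=chamber_volume_ml,
        tissue_mass_mg=tissue_mass_mg,
        mito_fraction=mito_fraction,
    )
    table = MitoStateTable(net=False)
    for name, t0, t1 in windows:
        if name is None:
            continue
        in_win = (trace.time >= t0) & (trace.time <= t1)
        if in_win.any() and trace.o2_conc[in_win][0] > low_o2_um:
            below = in_win & (trace.o2_conc < low_o2_um)
            if below.any():
                t1 = float(trace.time[below][0])
        lo, hi, flagged = _steady_window(trace.time, j, t0, t1)
        sel = (trace.time >= lo) & (trace.time <= hi)
        if sel.sum() < 3:
            table.notes.append(f"{name}: window too sparse, state skipped")
            continue
        jo2 = float(np.mean(j[sel]))
        dpsi = None
        if trace.fluorescence is not None:
            # measurement noise can push the bath mean past the physical
            # bound (total added dye); clip before the mass balance
            safr_out = float(np.mean(trace.fluorescence[sel]))
            safr_out = min(safr_out, total_safr_um)
            if safr_out > 0:
                safr_in = safr_in_from_mass_balance(total_safr_um, safr_out, params)
                dpsi = membrane_potential(safr_out, safr_in, params)
        table.states[name] = StateMeasure(
            jo2, dpsi, int(sel.sum()), flagged, "unsteady window" if flagged else ""
        )
    return table


def rox_correct(table: MitoStateTable) -> MitoStateTable:
    """Subtract residual (non-mitochondrial) consumption from every state.

    ROX (post-antimycin A) is the blank for all states except the
    cytochrome-c-oxidase pair: CCO's blank is the azide rate,
    ``cco_net = CCO_raw - AZ_background``.  Without a ROX state the table
    is returned uncorrected with a note.  Negative net fluxes are flagged,
    not dropped.
    """
    if table.net:
        raise ValueError("table is already ROX-corrected")
    out = MitoStateTable(net=True, notes=list(table.notes))
    if "ROX" not in table:
        out.net = False
        out.notes.append("no ROX state: fluxes left uncorrected")
        out.states = {k: StateMeasure(**vars(v)) for k, v in table.states.items()}
        rox = None
    else:
        rox = table.jo2("ROX")
        for name, m in table.states.items():
            if name in ("CCO_raw", "AZ_background", "ROX"):
                net = m.jo2 if name != "ROX" else 0.0
            else:
                net = m.jo2 - rox
            flagged = m.flagged or net < 0
            reason = m.flag_reason
            if net < 0:
                reason = (reason + "; " if reason else "") + "negative net flux"
            out.states[name] = StateMeasure(net, m.dpsi, m.n_samples, flagged, reason)
    if "CCO_raw" in table and "AZ_background" in table:
        out.cco_net = table.jo2("CCO_raw") - table.jo2("AZ_background")
    return out


def rcr(table: MitoStateTable) -> float:
    """Respiratory control ratio: CI+CII OXPHOS over CI+CII leak (net fluxes)."""
    for s in ("OXPHOS_CI_CII", "Leak_CI_CII"):
        if s not in table:
            raise InsufficientDataError(f"state {s} missing; cannot compute RCR")
    leak = table.jo2("Leak_CI_CII")
    if leak <= 0:
        raise ValueError("leak flux <= 0: RCR undefined")
    value = table.jo2("OXPHOS_CI_CII") / leak
    lo, hi = RCR_ADVISORY_RANGE
    if not (lo <= value <= hi):
        table.notes.append(
            f"RCR {value:.1f} outside the advisory {lo}-{hi} band for healthy "
            "heart preparations"
        )
    return value


# ------------------------------------------------------------ O2 kinetics --

def hill(po2, jmax: float, p50: float, h: float):
    """Hill saturation curve J(PO2) = Jmax * PO2^h / (P50^h + PO2^h)."""
    p = np.asarray(po2, dtype=float)
    return jmax * p**h / (p50**h + p**h)


def p50_segment(
    trace: MitoTrace,
    tissue_mass_mg: float,
    chamber_volume_ml: float,
    o2_max_um: float = 20.0,
    o2_min_um: float = 0.05,
    max_anoxia_s: float = 600.0,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """(O2 uM, JO2) pairs for the Hill fit from the post-succinate drawdown.

    Flux is the two-point chord slope of each sample pair ``stride``
    samples apart, paired with the interval-midpoint O2 — unsmoothed,
    because the drawdown is the one fast segment of the assay and kernel
    smoothing would bias the kinetics.  ``stride=1`` is exact on clean
    data; noisy traces want a longer chord (e.g. 10 s) to tame the
    differentiation noise.  Only the O2-limited region (midpoint O2 below
    ``o2_max_um``) is kept; the time spent below 1 uM is capped at
    ``max_anoxia_s``.
    """
    succ = trace.event_times("succinate")
    if not succ:
        raise InsufficientDataError("no succinate event: drawdown undefined")
    t0 = succ[0]
    later = [e.time for e in trace.events if e.time > t0]
    t1 = later[0] if later else float(trace.time[-1])
    sel = (trace.time >= t0) & (trace.time <= t1)
    t, c = trace.time[sel], trace.o2_conc[sel]
    if len(t) < 3:
        raise InsufficientDataError("drawdown segment too short")
    # cap the anoxic tail
    anoxic = np.where(c < 1.0)[0]
    if len(anoxic):
        t_cap = t[anoxic[0]] + max_anoxia_s
        keep = t <= t_cap
        t, c = t[keep], c[keep]
    if stride < 1 or stride >= len(t):
        raise ValueError("stride must be >= 1 and shorter than the segment")
    mid = 0.5 * (c[:-stride] + c[stride:])
    jo2 = (
        -((c[stride:] - c[:-stride]) / (t[stride:] - t[:-stride]))
        * 1000.0
        * chamber_volume_ml
        / tissue_mass_mg
    )
    keep = (mid <= o2_max_um) & (mid >= o2_min_um)
    if keep.sum() < 10:
        raise InsufficientDataError(
            f"only {int(keep.sum())} points in the O2-limited region; need >= 10"
        )
    return mid[keep], jo2[keep]


def fit_p50(
    po2: np.ndarray,
    jo2: np.ndarray,
    r2_threshold: float = 0.70,
    unit: str = "uM",
) -> P50Fit:
    """Least-squares Hill fit of flux against O2 pressure/concentration.

    Initialisation: P50 at the PO2 of half-maximal observed flux, h = 1,
    Jmax at the 95th-percentile flux; bounds keep h in [0.2, 10].  R2 is
    computed on the untransformed flux residuals; fits with R2 at or below
    ``r2_threshold`` are returned with ``accepted=False``.
    """
    p = np.asarray(po2, dtype=float)
    j = np.asarray(jo2, dtype=float)
    if len(p) < 10:
        raise InsufficientDataError("need >= 10 points for the Hill fit")
    if np.all(p < 1e-12):
        raise InsufficientDataError("all-anoxic segment: no kinetic information")
    jmax0 = float(np.percentile(j, 95))
    if jmax0 <= 0:
        jmax0 = max(float(j.max()), 1e-6)
    half = 0.5 * jmax0
    above = p[j >= half]
    p50_0 = float(above.min()) if len(above) else float(np.median(p))
    p50_0 = max(p50_0, 1e-6)
    try:
        popt, _ = curve_fit(
            hill,
            p,
            j,
            p0=[jmax0, p50_0, 1.0],
            bounds=([1e-9, 1e-9, 0.2], [np.inf, np.inf, 10.0]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit failed to converge (n={len(p)}, "
            f"po2 range {p.min():.3g}-{p.max():.3g}): {exc}"
        ) from exc
    resid = j - hill(p, *popt)
    ss_tot = float(np.sum((j - j.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return P50Fit(
        jmax=float(popt[0]),
        p50=float(popt[1]),
        hill_h=float(popt[2]),
        r2=r2,
        unit=unit,
        accepted=r2 > r2_threshold,
    )


# ------------------------------------------------------- membrane potential --

def safr_in_from_mass_balance(
    total_safr_um: float,
    safr_out_um: float,
    params: NernstParams,
) -> float:
    """Matrix safranin concentration from the bath depletion mass balance.

    All dye missing from the bath is taken up into the matrix:
    safr_in = safr_out + (total - out) * V_chamber / V_mito.
    """
    if not (0.0 < safr_out_um <= total_safr_um):
        raise ValueError("need 0 < safr_out <= total_safr")
    if params.v_mito_ul >= params.v_chamber_ul:
        raise ConfigurationError("matrix volume must be far below chamber volume")
    return safr_out_um + (total_safr_um - safr_out_um) * (
        params.v_chamber_ul / params.v_mito_ul
    )


def nernst_slope_mv(temperature_k: float, z: int = 1) -> float:
    """Nernst slope 2.3026*R*T/(z*F), in mV per decade of concentration ratio."""
    return LN10 * GAS_CONSTANT * temperature_k / (z * FARADAY) * 1000.0


def membrane_potential(
    safr_out_um: float,
    safr_in_um: float,
    params: NernstParams,
) -> float:
    """Nernst membrane potential, mV: dPsi = slope * log10(out/in).

    Matrix accumulation (in > out) gives a negative potential, matching
    the sign convention of energized mitochondria.
    """
    if safr_out_um <= 0 or safr_in_um <= 0:
        raise ValueError("dye concentrations must be > 0")
    return nernst_slope_mv(params.temperature_k, params.z) * float(
        np.log10(safr_out_um / safr_in_um)
    )


def mito_work(jo2: float, dpsi: float) -> float:
    """Respiratory work index JO2 / (-dPsi), pmol O2 s-1 mg-1 mV-1."""
    if dpsi == 0:
        raise ValueError("dPsi = 0: work undefined")
    return jo2 / (-dpsi)
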