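"""Seeded synthetic-data generators with paired ground truth.

Each generator emulates one input class of the analysis pipeline —
intermittent-flow respirometry cycles, a closed hypoxia drawdown, a
post-hypoxia recovery curve, and a full titration-protocol mitochondrial
assay — and returns the generated record together with the exact
parameters it encodes, so every estimator can be validated by parameter
recovery without any external data.

Default parameter values are anchored to the group means of the study
conditions the package targets: SMR 132.3 and MMR 464.2 mg O2 kg-1 h-1,
Pcrit 5.4 kPa and PLOE 2.8 kPa at 21 degC / 35 ppt, and CI / CI+CII
OXPHOS fluxes of 53.3 / 66.3 pmol s-1 mg-1 with a -147.5 mV CI-OXPHOS
membrane potential.

Two constructions matter for exactness.  Measure-phase declines and the
oxyregulating drawdown are linear, so OLS slopes recover the encoded rate
to machine precision.  Curved segments (the oxyconforming drawdown and
the Hill-limited anoxia approach) are stepped with a midpoint-implicit
rule: each consecutive sample pair satisfies
(C_n - C_{n+1})/dt = rate((C_n + C_{n+1})/2) exactly, so the analysis's
two-point chord slope paired with the interval-midpoint level lies exactly
on the generating model, and noise-free round trips are exact rather than
quadrature-limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .traces import (
    ConfigurationError,
    MitoTrace,
    OxygenTrace,
    RespirometrySetup,
    TitrationEvent,
)
from .units import percent_sat_to_po2, po2_to_percent_sat
from .whole_animal import MO2Entry, MO2Series
from .mito import NernstParams, nernst_slope_mv

__all__ = [
    "GENERATOR_VERSION",
    "SyntheticGroundTruth",
    "default_setup",
    "gen_respirometry_trace",
    "gen_hypoxia_trace",
    "gen_drawdown_points",
    "gen_recovery_series",
    "gen_mito_trace",
]

GENERATOR_VERSION = "1.0"


@dataclass
class SyntheticGroundTruth:
    """True parameters a generated record encodes, for recovery testing."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    version: str = GENERATOR_VERSION


def default_setup(temperature: float = 21.0, vr_l: float = 4.3) -> RespirometrySetup:
    """Chamber/fish configuration matching the study's mean animal."""
    return RespirometrySetup(
        vr_l=vr_l, mb_kg=0.114, temperature=temperature, salinity=35.0
    )


def _sat_rate_per_hour(mo2: float, setup: RespirometrySetup) -> float:
    """%sat h-1 decline implied by a mass-specific uptake rate (inverse MO2)."""
    return mo2 * setup.mb_kg / ((setup.vr_l - setup.vf_l) * setup.alpha)


# ------------------------------------------------------ whole-animal trace --

def gen_respirometry_trace(
    smr: float = 132.3,
    mmr: float = 464.2,
    setup: Optional[RespirometrySetup] = None,
    flush_s: float = 300.0,
    wait_s: float = 90.0,
    measure_s: float = 300.0,
    sample_dt: float = 5.0,
    n_rest_cycles: int = 60,
    n_chase_cycles: int = 10,
    noise_sd: float = 0.0,
    background_pre: float = -0.5,
    background_post: float = -2.0,
    burst_prob: float = 0.25,
    burst_lognorm: tuple[float, float] = (-1.2, 0.8),
    burst_tau_s: float = 600.0,
    settle_frac: float = 0.5,
    settle_tau_s: float = 7200.0,
    recovery_tau_s: float = 1800.0,
    seed: int = 0,
) -> tuple[OxygenTrace, SyntheticGroundTruth]:
    """Cyclic flush/wait/measure trace around a target SMR, plus a chase.

    Rest cycles settle exponentially toward ``smr`` with lognormal
    multiplicative activity bursts (exponentially decaying between cycles);
    the chase block starts exactly at ``mmr`` and decays back toward SMR.
    Background respiration drifts linearly from ``background_pre`` to
    ``background_post`` (%sat h-1) across the record and is added to every
    sealed-phase decline; Gaussian sensor noise is ``noise_sd`` %sat.
    """
    if not smr < mmr:
        raise ValueError("need smr < mmr")
    setup = setup or default_setup()
    rng = np.random.default_rng(seed)
    cycle_s = flush_s + wait_s + measure_s
    total_s = (n_rest_cycles + n_chase_cycles) * cycle_s

    times, o2, phases = [], [], []
    cycle_truth = []
    burst = 0.0
    t = 0.0
    level = 100.0

    def bg_rate(at: float) -> float:
        return background_pre + (background_post - background_pre) * at / total_s

    for i in range(n_rest_cycles + n_chase_cycles):
        if i < n_rest_cycles:
            burst *= np.exp(-cycle_s / burst_tau_s)
            if rng.random() < burst_prob:
                burst += rng.lognormal(*burst_lognorm)
            settle = settle_frac * np.exp(-t / settle_tau_s)
            m = min(smr * (1.0 + settle + burst), 0.9 * mmr)
        else:
            dt_chase = (i - n_rest_cycles) * cycle_s
            m = smr + (mmr - smr) * np.exp(-dt_chase / recovery_tau_s)
        cycle_truth.append(m)
        fish_rate = _sat_rate_per_hour(m, setup)

        for phase, dur in (("flush", flush_s), ("wait", wait_s), ("measure", measure_s)):
            n = int(round(dur / sample_dt))
            for k in range(n):
                tk = t + k * sample_dt
                if phase == "flush":
                    level = 100.0
                    val = level
                else:
                    # midpoint-rule step: exact integral of the linearly
                    # drifting background, so samples lie on the quadratic
                    val = level
                    level = val - (fish_rate - bg_rate(tk + sample_dt / 2.0)) * (
                        sample_dt / 3600.0
                    )
                if val <= 0:
                    raise ValueError(
                        "parameters imply sub-zero O2 within a cycle; reduce "
                        "metabolic rate or cycle length"
                    )
                times.append(tk)
                o2.append(val)
                phases.append(phase)
            t += dur

    o2 = np.asarray(o2, dtype=float)
    if noise_sd > 0:
        o2 = np.clip(o2 + rng.normal(0.0, noise_sd, len(o2)), 0.0, None)
    trace = OxygenTrace(np.asarray(times), o2, setup.temperature, np.asarray(phases, dtype=object))
    truth = SyntheticGroundTruth(
        "respirometry",
        seed,
        {
            "smr": smr,
            "mmr": mmr,
            "cycle_mo2": cycle_truth,
            "background_pre": background_pre,
            "background_post": background_post,
            "noise_sd": noise_sd,
            "t_pre": 0.0,
            "t_post": total_s,
        },
    )
    return trace, truth


# ------------------------------------------------------------ hypoxia trace --

def gen_hypoxia_trace(
    smr: float = 132.3,
    pcrit_kpa: float = 5.4,
    ploe_kpa: float = 2.8,
    setup: Optional[RespirometrySetup] = None,
    conform_slope: Optional[float] = None,
    start_sat: float = 100.0,
    sample_dt: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[OxygenTrace, SyntheticGroundTruth]:
    """Closed drawdown with an exact oxyregulation-to-conformation breakpoint.

    Above Pcrit the fish holds MO2 = SMR (linear decline); below it MO2
    follows the line through (Pcrit, SMR) with slope ``conform_slope``
    (MO2 per kPa; default SMR/Pcrit, i.e. through the origin).  A sample
    is placed exactly at the breakpoint, and sub-breakpoint samples are
    stepped midpoint-implicitly, so interval chord slopes lie exactly on
    the conforming line.  The LOE annotation time is where the trace
    linearly interpolates to PLOE.
    """
    if not ploe_kpa < pcrit_kpa:
        raise ValueError("need ploe < pcrit")
    setup = setup or default_setup(vr_l=1.9)
    rng = np.random.default_rng(seed)
    beta = percent_sat_to_po2(100.0, setup.temperature, setup.barometric_pressure) / 100.0
    pcrit_sat = pcrit_kpa / beta
    ploe_sat = ploe_kpa / beta
    if start_sat <= pcrit_sat:
        raise ValueError("start saturation must exceed the breakpoint")
    k = smr / pcrit_kpa if conform_slope is None else conform_slope
    intercept = smr - k * pcrit_kpa  # MO2 at PO2 = 0
    f = setup.mb_kg / ((setup.vr_l - setup.vf_l) * setup.alpha)
    a, b = intercept * f, k * beta * f  # sat rate = a + b * sat
    dt_h = sample_dt / 3600.0

    times = [0.0]
    sats = [start_sat]
    r_reg = smr * f  # %sat h-1 while regulating
    t, s = 0.0, start_sat
    while s - r_reg * dt_h > pcrit_sat:
        s -= r_reg * dt_h
        t += sample_dt
        times.append(t)
        sats.append(s)
    # land a sample exactly on the breakpoint
    t += (s - pcrit_sat) / r_reg * 3600.0
    s = pcrit_sat
    times.append(t)
    sats.append(s)
    # conforming: midpoint-implicit linear-rate recursion
    stop_sat = 0.85 * ploe_sat
    while s > stop_sat:
        s = (s * (1.0 - b * dt_h / 2.0) - a * dt_h) / (1.0 + b * dt_h / 2.0)
        if s <= 0:
            break
        t += sample_dt
        times.append(t)
        sats.append(s)

    sats = np.asarray(sats)
    times = np.asarray(times)
    # annotation: linear interpolation to PLOE between bracketing samples
    loe_time = float(np.interp(-ploe_sat, -sats, times))
    if noise_sd > 0:
        sats = np.clip(sats + rng.normal(0.0, noise_sd, len(sats)), 0.0, None)
    trace = OxygenTrace(
        times, sats, setup.temperature, np.full(len(times), "closed_hypoxia", dtype=object)
    )
    truth = SyntheticGroundTruth(
        "hypoxia",
        seed,
        {
            "smr": smr,
            "pcrit_kpa": pcrit_kpa,
            "ploe_kpa": ploe_kpa,
            "loe_time": loe_time,
            "conform_slope": k,
            "conform_intercept": intercept,
            "noise_sd": noise_sd,
        },
    )
    return trace, truth


def gen_drawdown_points(
    smr: float = 135.0,
    pcrit_kpa: float = 5.4,
    n_points: int = 20,
    noise_sd: float = 5.0,
    po2_min: float = 0.3,
    conform_slope: Optional[float] = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticGroundTruth]:
    """Direct (PO2, MO2) oxyconforming points for breakpoint-estimator studies.

    Gaussian noise of ``noise_sd`` (mg O2 kg-1 h-1) is applied to MO2; the
    noise-free points lie exactly on the conforming line.
    """
    rng = np.random.default_rng(seed)
    k = smr / pcrit_kpa if conform_slope is None else conform_slope
    intercept = smr - k * pcrit_kpa
    po2 = np.linspace(po2_min, pcrit_kpa * 0.98, n_points)
    mo2 = intercept + k * po2 + rng.normal(0.0, noise_sd, n_points)
    truth = SyntheticGroundTruth(
        "drawdown_points",
        seed,
        {"smr": smr, "pcrit_kpa": pcrit_kpa, "slope": k, "intercept": intercept},
    )
    return po2, mo2, truth


# ----------------------------------------------------------- recovery curve --

def gen_recovery_series(
    smr: float = 132.3,
    peak_excess: float = 200.0,
    tau_h: float = 1.0,
    sample_dt_h: float = 0.2,
    noise_sd: float = 0.0,
    min_excess: float = 1.0,
    seed: int = 0,
) -> tuple[MO2Series, SyntheticGroundTruth]:
    """Exponential post-hypoxia recovery: MO2(t) = 1.1*SMR + A*exp(-t/tau).

    Sampling continues until the excess falls below ``min_excess``; the
    analytic debt over the sampled span, A*tau*(1 - exp(-T/tau)), is
    recorded as ground truth.
    """
    if peak_excess < 0 or tau_h <= 0:
        raise ValueError("need peak_excess >= 0 and tau_h > 0")
    rng = np.random.default_rng(seed)
    thr = 1.10 * smr
    times = [0.0]
    while peak_excess > 0 and peak_excess * np.exp(-times[-1] / tau_h) >= min_excess:
        times.append(times[-1] + sample_dt_h)
    t = np.asarray(times)
    v = thr + peak_excess * np.exp(-t / tau_h)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, len(v))
    series = MO2Series([MO2Entry(float(ti) * 3600.0, float(vi), True, True) for ti, vi in zip(t, v)])
    debt = peak_excess * tau_h * (1.0 - np.exp(-t[-1] / tau_h))
    truth = SyntheticGroundTruth(
        "recovery",
        seed,
        {
            "smr": smr,
            "threshold": thr,
            "peak_excess": peak_excess,
            "tau_h": tau_h,
            "span_h": float(t[-1]),
            "total_debt": float(debt),
        },
    )
    return series, truth


# -------------------------------------------------------------- mito trace --

_DEFAULT_NET_FLUXES = {
    "Leak_CI": 5.0,
    "OXPHOS_CI": 53.3,
    "OXPHOS_CI_CII": 66.3,
    "Leak_CI_CII": 4.4,
    "ETS_uncoupled": 70.0,
}

_DEFAULT_DPSI = {
    "Leak_CI": -155.0,
    "OXPHOS_CI": -147.5,
    "OXPHOS_CI_CII": -145.6,
    "Leak_CI_CII": -150.0,
    "ETS_uncoupled": -60.0,
}

_EVENT_CONCS = {
    "pyruvate": (5.0, "mM"),
    "malate": (2.0, "mM"),
    "ADP": (2.5, "mM"),
    "succinate": (10.0, "mM"),
    "H2O2": (5.0, "uL"),
    "catalase": (5.0, "U/mL"),
    "oligomycin": (10.0, "nM"),
    "CCCP": (0.1, "uM"),
    "antimycin_a": (2.5, "uM"),
    "ascorbate": (2.0, "mM"),
    "TMPD": (0.5, "mM"),
    "azide": (100.0, "mM"),
}


def _safr_out_for_dpsi(dpsi: float, total_um: float, params: NernstParams) -> float:
    """Invert the Nernst + mass-balance pair: bath dye level for a target dPsi."""
    if dpsi == 0.0:
        return total_um
    ratio = 10.0 ** (-dpsi / nernst_slope_mv(params.temperature_k, params.z))
    return total_um / (1.0 + (ratio - 1.0) * params.v_mito_ul / params.v_chamber_ul)


def gen_mito_trace(
    state_fluxes: Optional[dict] = None,
    p50: float = 2.0,
    hill_h: float = 1.5,
    dpsi_per_state: Optional[dict] = None,
    rox_flux: float = 2.0,
    az_flux: float = 15.0,
    cco_net: float = 165.0,
    tissue_mg: float = 5.0,
    chamber_ml: float = 2.0,
    temperature: float = 21.0,
    total_safr_um: float = 2.0,
    mito_fraction: float = 0.198,
    o2_start_um: float = 200.0,
    reox_to_um: float = 350.0,
    hill_onset_um: float = 25.0,
    anoxia_hold_s: float = 120.0,
    state_dur_s: float = 300.0,
    sample_dt: float = 1.0,
    noise_sd: float = 0.0,
    noise_sd_fluor: float = 0.0,
    seed: int = 0,
) -> tuple[MitoTrace, SyntheticGroundTruth]:
    """Full titration-protocol assay trace with Hill O2 kinetics near anoxia.

    ``state_fluxes`` are net (ROX-subtracted) fluxes, pmol s-1 mg-1; the
    chamber consumes at net + ``rox_flux`` in each state (the CCO step at
    ``cco_net`` + ``az_flux``, blanked by azide).  Oxygen is integrated at
    ``sample_dt`` with a fixed-step scheme: constant flux above
    ``hill_onset_um``, midpoint-implicit Hill-limited flux below it during
    the post-succinate drawdown.  The safranin channel is piecewise
    constant at the bath concentration that reproduces each state's target
    membrane potential through the matrix mass balance.
    """
    net = dict(_DEFAULT_NET_FLUXES, **(state_fluxes or {}))
    dpsi = dict(_DEFAULT_DPSI, **(dpsi_per_state or {}))
    if not (net["OXPHOS_CI_CII"] >= net["Leak_CI_CII"] >= 0 and net["OXPHOS_CI"] >= net["Leak_CI"] >= 0):
        raise ValueError("fluxes must be ordered OXPHOS >= Leak >= 0")
    if not cco_net >= net["OXPHOS_CI_CII"]:
        raise ValueError("CCO capacity must be >= OXPHOS flux")
    rng = np.random.default_rng(seed)
    params = NernstParams(
        temperature_k=temperature + 273.15,
        chamber_volume_ml=chamber_ml,
        tissue_mass_mg=tissue_mg,
        mito_fraction=mito_fraction,
    )
    to_rate = tissue_mg / (chamber_ml * 1000.0)  # pmol/s/mg -> uM/s

    times: list[float] = []
    o2: list[float] = []
    fluor: list[float] = []
    events: list[TitrationEvent] = []

    t = 0.0
    c = o2_start_um

    def emit(reagent: str, at: float) -> None:
        conc, unit = _EVENT_CONCS[reagent]
        events.append(TitrationEvent(at, reagent, conc, unit))

    def run_linear(duration: float, flux_raw: float, safr_out: float) -> None:
        nonlocal t, c
        rate = flux_raw * to_rate
        n = int(round(duration / sample_dt))
        for _ in range(n):
            times.append(t)
            o2.append(c)
            fluor.append(safr_out)
            c = max(c - rate * sample_dt, 0.0)
            t += sample_dt

    def run_hill_drawdown(flux_raw: float, safr_out: float) -> None:
        """Constant flux above the Hill onset, midpoint-implicit Hill below."""
        nonlocal t, c
        rate_max = flux_raw * to_rate

        def rate(x: float) -> float:
            return rate_max * x**hill_h / (p50**hill_h + x**hill_h)

        # linear part
        while c - rate_max * sample_dt > hill_onset_um:
            times.append(t)
            o2.append(c)
            fluor.append(safr_out)
            c -= rate_max * sample_dt
            t += sample_dt
        # Hill-limited part, then a fixed anoxia hold
        t_anoxic: Optional[float] = None
        while True:
            times.append(t)
            o2.append(c)
            fluor.append(safr_out)
            g = lambda x: (c - x) / sample_dt - rate((c + x) / 2.0)
            # g(c) < 0 (still consuming), g(0) > 0 unless already at 0
            if c <= 1e-9:
                nxt = 0.0
            elif g(0.0) <= 0:
                nxt = 0.0
            else:
                nxt = brentq(g, 0.0, c, xtol=1e-15, rtol=8.9e-16)
            c = nxt
            t += sample_dt
            if c < 1.0 and t_anoxic is None:
                t_anoxic = t
            if t_anoxic is not None and t - t_anoxic >= anoxia_hold_s:
                break

    raw = {k: v + rox_flux for k, v in net.items()}
    safr = {k: _safr_out_for_dpsi(dpsi.get(k, 0.0), total_safr_um, params) for k in net}
    safr_baseline = total_safr_um

    # baseline (tissue + dye, no substrate): residual consumption only
    run_linear(120.0, rox_flux, safr_baseline)
    emit("pyruvate", t)
    run_linear(5.0, rox_flux, safr_baseline)
    emit("malate", t)
    run_linear(state_dur_s, raw["Leak_CI"], safr["Leak_CI"])
    emit("ADP", t)
    run_linear(state_dur_s, raw["OXPHOS_CI"], safr["OXPHOS_CI"])
    emit("succinate", t)
    run_hill_drawdown(raw["OXPHOS_CI_CII"], safr["OXPHOS_CI_CII"])
    emit("H2O2", t)
    emit("catalase", t + 1.0)
    c = reox_to_um  # catalase liberates O2 from the peroxide bolus
    run_linear(180.0, raw["OXPHOS_CI_CII"], safr["OXPHOS_CI_CII"])
    emit("oligomycin", t)
    run_linear(state_dur_s, raw["Leak_CI_CII"], safr["Leak_CI_CII"])
    emit("CCCP", t)
    run_linear(state_dur_s, raw["ETS_uncoupled"], safr["ETS_uncoupled"])
    emit("antimycin_a", t)
    run_linear(state_dur_s, rox_flux, safr_baseline)
    emit("ascorbate", t)
    run_linear(5.0, rox_flux, safr_baseline)
    emit("TMPD", t)
    run_linear(state_dur_s, cco_net + az_flux, safr_baseline)
    emit("azide", t)
    run_linear(state_dur_s, az_flux, safr_baseline)
    # final sample closes the last interval
    times.append(t)
    o2.append(c)
    fluor.append(safr_baseline)

    o2_arr = np.asarray(o2)
    fl_arr = np.asarray(fluor)
    if noise_sd > 0:
        o2_arr = np.clip(o2_arr + rng.normal(0.0, noise_sd, len(o2_arr)), 0.0, None)
    if noise_sd_fluor > 0:
        fl_arr = np.clip(fl_arr + rng.normal(0.0, noise_sd_fluor, len(fl_arr)), 1e-6, None)
    trace = MitoTrace(np.asarray(times), o2_arr, events, fl_arr, temperature)
    truth = SyntheticGroundTruth(
        "mito",
        seed,
        {
            "net_fluxes": net,
            "raw_fluxes": raw,
            "rox_flux": rox_flux,
            "az_flux": az_flux,
            "cco_net": cco_net,
            "p50": p50,
            "hill_h": hill_h,
            "jmax_raw": raw["OXPHOS_CI_CII"],
            "dpsi_per_state": dpsi,
            "rcr": net["OXPHOS_CI_CII"] / net["Leak_CI_CII"],
            "total_safr_um": total_safr_um,
            "tissue_mg": tissue_mg,
            "chamber_ml": chamber_ml,
            "noise_sd": noise_sd,
        },
    )
    return trace, truth
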