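"""End-to-end study orchestration: per-fish assessment and group reporting.

Each fish in the study runs the same 2.5-day assessment: overnight
intermittent-flow respirometry (SMR), a closed hypoxia challenge (Pcrit,
PLOE), overnight recovery (oxygen debt), an exhaustive chase (MMR), then
tissue sampling and a heart mitochondrial assay.  :func:`run_study`
replays that analysis over a manifest of per-fish inputs, isolates
per-fish failures, and produces group mean +/- SE tables with the
percent-change summaries against the pooled controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import hypoxia as hx
from . import indices as ix
from . import mito as mt
from . import whole_animal as wa
from .traces import MitoTrace, OxygenTrace, RespirometrySetup

__all__ = ["FishInputs", "StudyManifest", "run_study"]

#: Temperature of each treatment group, degC.
GROUP_TEMPERATURE = {
    "control_start": 21.0,
    "d1_25C": 25.0,
    "d10_25C": 25.0,
    "d30_25C": 25.0,
    "control_end": 21.0,
}


@dataclass
class FishInputs:
    """Everything recorded for one fish.  Optional pieces are skipped."""

    fish_id: str
    treatment: str
    setup: RespirometrySetup
    resp_trace: Optional[OxygenTrace] = None
    background: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)  # pre, post, t_pre, t_post
    hypoxia_trace: Optional[OxygenTrace] = None
    loe_time: Optional[float] = None
    recovery: Optional[wa.MO2Series] = None
    record: Optional[ix.FishRecord] = None
    mito_trace: Optional[MitoTrace] = None
    tissue_mg: float = 5.0
    chamber_ml: float = 2.0
    total_safr_um: float = 2.0


@dataclass
class StudyManifest:
    fish: list[FishInputs] = field(default_factory=list)
    salinity: float = 35.0

    def __post_init__(self) -> None:
        if not self.fish:
            raise ValueError("empty manifest")
        bad = {f.treatment for f in self.fish} - set(ix.TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatments: {sorted(bad)}")


def _analyze_fish(fi: FishInputs, log: list[str]) -> dict:
    out: dict = {"fish_id": fi.fish_id, "treatment": fi.treatment}
    smr = None
    if fi.resp_trace is not None:
        cycles = wa.extract_cycle_slopes(fi.resp_trace)
        pre, post, t0, t1 = fi.background
        cycles = wa.background_correct(cycles, pre, post, t0, t1)
        series = wa.mo2_series(cycles, fi.setup)
        smr, n_used = wa.estimate_smr(series)
        mmr, t_mmr = wa.estimate_mmr(series)
        out.update(smr=smr, smr_n_used=n_used, mmr=mmr, ms=wa.aerobic_scope(smr, mmr))
        log.append(f"{fi.fish_id}: {len(cycles)} cycles, SMR n={n_used}, MMR at t={t_mmr:.0f}s")
    if fi.hypoxia_trace is not None and smr is not None:
        po2, mo2 = hx.drawdown_series(fi.hypoxia_trace, fi.setup, bin_s=120.0)
        res = hx.detect_pcrit(po2, mo2, smr)
        out["pcrit_kpa"] = res.pcrit
        log.append(f"{fi.fish_id}: Pcrit from {res.n_conforming_points} conforming points")
        if fi.loe_time is not None:
            out["ploe_kpa"] = hx.detect_ploe(
                fi.hypoxia_trace, fi.loe_time, fi.setup.barometric_pressure
            )
    if fi.recovery is not None and smr is not None:
        ep = hx.epoc_metrics(fi.recovery.times / 3600.0, fi.recovery.values, smr)
        out.update(
            epoc_peak=ep.peak_mo2,
            epoc_total_debt=ep.total_debt,
            epoc_recovery_h=ep.recovery_time,
            epoc_debt_per_h=ep.debt_per_hour,
        )
        if ep.right_censored:
            log.append(f"{fi.fish_id}: recovery right-censored; debt to last sample")
    if fi.record is not None:
        r = fi.record
        out["condition_factor"] = ix.condition_factor(r.mb_kg, r.fork_length_m)
        if r.ventricle_mass_kg:
            out["rel_ventricle_mass"] = ix.relative_organ_mass(r.ventricle_mass_kg, r.mb_kg)
        if r.spleen_mass_kg:
            out["rel_spleen_mass"] = ix.relative_organ_mass(r.spleen_mass_kg, r.mb_kg)
        if r.liver_mass_kg:
            out["rel_liver_mass"] = ix.relative_organ_mass(r.liver_mass_kg, r.mb_kg)
        if r.hct_pct is not None:
            out["hct"] = r.hct_pct
        if r.hb_g_l is not None:
            out["hb"] = r.hb_g_l
        if r.hct_pct is not None and r.hb_g_l is not None:
            out["mch"] = ix.mch(r.hb_g_l, r.hct_pct)
    if fi.mito_trace is not None:
        raw = mt.extract_states(
            fi.mito_trace, fi.tissue_mg, fi.chamber_ml, fi.total_safr_um
        )
        net = mt.rox_correct(raw)
        for state in ("Leak_CI", "OXPHOS_CI", "OXPHOS_CI_CII", "Leak_CI_CII", "ETS_uncoupled"):
            if state in net:
                out[f"jo2_{state}"] = net.jo2(state)
                d = net.dpsi(state)
                if d is not None:
                    out[f"dpsi_{state}"] = d
                    out[f"work_{state}"] = mt.mito_work(net.jo2(state), d)
        if net.cco_net is not None:
            out["cco_net"] = net.cco_net
        try:
            out["rcr"] = mt.rcr(net)
        except (ValueError, mt.InsufficientDataError) as exc:
            log.append(f"{fi.fish_id}: RCR unavailable ({exc})")
        try:
            po2, jo2 = mt.p50_segment(fi.mito_trace, fi.tissue_mg, fi.chamber_ml)
            fit = mt.fit_p50(po2, jo2)
            if fit.accepted:
                out["p50_um"] = fit.p50
                out["p50_r2"] = fit.r2
            else:
                log.append(f"{fi.fish_id}: Hill fit rejected (R2={fit.r2:.2f})")
        except (mt.InsufficientDataError, RuntimeError) as exc:
            log.append(f"{fi.fish_id}: P50 unavailable ({exc})")
    return out


def run_study(
    manifest: StudyManifest,
    out_dir: Optional[str | Path] = None,
    pool_controls: bool = True,
    no_pool_metrics: tuple[str, ...] = ("rel_liver_mass",),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[str]]:
    """Run the full per-fish analysis and group summarisation.

    Returns (per_fish table, {metric: group summary}, log).  Per-fish
    failures are isolated: the run continues and the failure is logged.
    The two 21 degC control groups are pooled per metric unless the metric
    is listed in ``no_pool_metrics``.
    """
    log: list[str] = []
    rows = []
    for fi in manifest.fish:
        try:
            rows.append(_analyze_fish(fi, log))
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            log.append(f"{fi.fish_id}: FAILED ({type(exc).__name__}: {exc})")
    if not rows:
        raise ValueError("every fish failed; nothing to summarise")
    per_fish = pd.DataFrame(rows)

    summaries: dict[str, pd.DataFrame] = {}
    metric_cols = [c for c in per_fish.columns if c not in ("fish_id", "treatment")]
    for col in metric_cols:
        df = per_fish[["treatment", col]].dropna()
        if df.empty:
            continue
        group_col = df["treatment"].copy()
        if pool_controls and col not in no_pool_metrics:
            group_col = group_col.replace(
                {"control_start": "control", "control_end": "control"}
            )
        summaries[col] = ix.group_summary(
            pd.DataFrame({"group": group_col, col: df[col]}), by="group", metric=col
        )

    # percent-change reporting vs the (pooled) control for the headline rates
    changes = {}
    for col in ("smr", "mmr", "ms"):
        if col in summaries and "control" in summaries[col].index:
            s = summaries[col]
            treats = [g for g in ("d1_25C", "d10_25C", "d30_25C") if g in s.index]
            if treats:
                changes[col] = ix.percent_change_summary(
                    s.loc["control", "mean"], [s.loc[g, "mean"] for g in treats]
                )
    if changes:
        summaries["percent_change_vs_control"] = pd.DataFrame(
            {"percent_change": changes}
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_fish.to_csv(out / "per_fish.csv", index=False)
        for name, df in summaries.items():
            df.to_csv(out / f"summary_{name}.csv")
        (out / "study.json").write_text(
            json.dumps(
                {
                    "per_fish": per_fish.to_dict(orient="records"),
                    "summaries": {k: v.to_dict() for k, v in summaries.items()},
                },
                indent=2,
                default=float,
            )
        )
        (out / "log.txt").write_text("\n".join(log) + "\n")
    return per_fish, summaries, log
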