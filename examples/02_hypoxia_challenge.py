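"""Closed hypoxia drawdown: Pcrit, PLOE and the post-hypoxia oxygen debt.

The fish draws its sealed chamber down; above Pcrit it oxyregulates
(holds SMR), below it oxyconforms.  Pcrit is the SMR-intercept of the
regression through the oxyconforming points; PLOE is the PO2 at the
annotated loss of equilibrium; the oxygen debt is the area of the
recovery curve above SMR + 10%.
"""

from aquaresp import hypoxia as hx
from aquaresp import synthetic as sy

setup = sy.default_setup(vr_l=1.9)
trace, truth = sy.gen_hypoxia_trace(
    smr=132.3, pcrit_kpa=5.4, ploe_kpa=2.8, setup=setup, noise_sd=0.1, seed=42
)

po2, mo2 = hx.drawdown_series(trace, setup, bin_s=120.0)
result = hx.detect_pcrit(po2, mo2, smr=132.3)
ploe = hx.detect_ploe(trace, truth.params["loe_time"])

print(f"drawdown duration : {trace.time[-1] / 60:5.1f} min")
print(f"Pcrit             : {result.pcrit:5.2f} kPa  (true {truth.params['pcrit_kpa']})")
print(f"  from {result.n_conforming_points} oxyconforming points, "
      f"slope {result.regression_slope:.1f} mg kg-1 h-1 per kPa")
print(f"PLOE              : {ploe:5.2f} kPa  (true {truth.params['ploe_kpa']})")

recovery, rtruth = sy.gen_recovery_series(smr=132.3, peak_excess=200.0, tau_h=1.0, seed=42)
ep = hx.epoc_metrics(recovery.times / 3600.0, recovery.values, 132.3)
print(f"recovery peak MO2 : {ep.peak_mo2:6.1f} mg O2 kg-1 h-1")
print(f"total O2 debt     : {ep.total_debt:6.1f} mg O2 kg-1 "
      f"(closed form {rtruth.params['total_debt']:.1f})")
print(f"time to threshold : {ep.recovery_time:6.2f} h   "
      f"debt repaid per h: {ep.debt_per_hour:6.1f}")
print()
print("Pcrit > PLOE: the fish stops regulating before it loses equilibrium;")
print("the debt quantifies the anaerobic cost repaid during re-oxygenation.")
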