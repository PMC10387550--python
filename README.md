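# aquaresp

Analysis tools for ecophysiological metabolic phenotyping of aquatic
ectotherms — the kind of 2.5-day assessment used to test how fish cope
with warming and hypoxia, from whole-animal oxygen uptake down to heart
mitochondria.  The package is aimed at comparative physiologists who run
intermittent-flow respirometry and high-resolution (O2k-style)
mitochondrial assays and want a scripted, testable replacement for
spreadsheet post-processing.

## What it computes

**Whole-animal respirometry.**  During each sealed measure phase of an
intermittent-flow cycle, oxygen declines linearly and the mass-specific
uptake rate follows from the slope:

    MO2 = (Vr − Vf) · |Δ%Sat/Δt| · α / Mb        [mg O2 kg⁻¹ h⁻¹]

with chamber and fish volume `Vr`, `Vf` (L), O2 solubility `α`
(mg O2 L⁻¹ per % air saturation, Garcia–Gordon fit) and body mass `Mb`
(kg).  Background (bacterial) respiration is interpolated linearly
between empty-chamber measurements and subtracted per cycle.  From the
resulting series: SMR (mean of the 10 lowest accepted values), MMR
(maximum, after an exhaustive chase), aerobic scope MS = MMR − SMR, and
Q10 = (R₂/R₁)^(10/ΔT).

**Hypoxia tolerance.**  In a closed drawdown the fish oxyregulates above
the critical oxygen pressure and oxyconforms below it.  P_crit is the
PO2 where the OLS regression through the oxyconforming points intercepts
SMR; P_LOE is the PO2 at the annotated loss of equilibrium.  The oxygen
debt repaid after re-oxygenation (EPOC) is the trapezoidal area of the
recovery curve above a threshold of SMR + 10%.

**Mitochondrial assays.**  A substrate–inhibitor–uncoupler titration
(pyruvate/malate → ADP → succinate → anoxia → reoxygenation → oligomycin
→ CCCP → antimycin A → TMPD/ascorbate → azide) yields per-state 2-minute
flux averages JO2 = −d[O2]/dt · V/m, ROX-corrected, with
RCR = OXPHOS_CI+CII / Leak_CI+CII, CCO net = (TMPD+Asc) − azide, Hill
oxygen kinetics J(PO2) = Jmax·PO2^h/(P50^h + PO2^h) gated at R² > 0.70,
and membrane potential from safranin distribution via the Nernst
equation ΔΨm = 2.3026·RT/(zF) · log10(safr_out/safr_in), where safr_in
follows from a bath-depletion mass balance over the matrix volume
(19.8 % of tissue volume).  Respiratory work is JO2/−ΔΨm.

**Synthetic data.**  `aquaresp.synthetic` generates every input class
with paired ground truth (seeded, byte-reproducible), so all estimators
are testable without instrument data.

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/01_whole_animal_respirometry.py` prints:

```
cycles analysed      : 68
SMR  (lowest 9 mean):   133.5 mg O2 kg-1 h-1  (true 132.3)
MMR  (max, post-chase):   464.5 mg O2 kg-1 h-1  (true 464.2)
MS   (MMR - SMR)      :   331.0 mg O2 kg-1 h-1
```

i.e. from a noisy synthetic overnight record encoding a true SMR of
132.3 the lowest-10 estimator recovers 133.5 (within 1 %), the first
post-chase cycle recovers MMR almost exactly, and the scope is their
difference.  `02_hypoxia_challenge.py` recovers P_crit 5.38 kPa /
P_LOE 2.82 kPa from a 49-minute drawdown encoding 5.4 / 2.8;
`03_mitochondrial_assay.py` prints the full state table (e.g. CI OXPHOS
53.3 pmol s⁻¹ mg⁻¹ at −147.5 mV, RCR ≈ 15, P50 ≈ 2 µM) and
`04_full_study.py` assembles group mean ± SE tables with percent changes
against a pooled control.

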