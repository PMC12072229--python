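# renalpbpk

Whole-body physiologically-based pharmacokinetic (PBPK) simulation of
renally secreted drugs, built around a permeability-limited mechanistic
kidney model. The package exists to answer two questions that matter for
drugs cleared by the renal organic anion transporter OAT1:

* **Transporter DDI** — how much does an OAT1/3 inhibitor such as
  probenecid raise the exposure of an OAT1 probe substrate such as
  adefovir, when the inhibitor's in vivo potency (unbound Ki) has been
  estimated from an endogenous biomarker rather than a dedicated trial?
* **Renal impairment** — how do exposure and renal clearance change across
  chronic kidney disease (CKD) stages, when tubular secretion declines
  *faster* than glomerular filtration?

It is aimed at PK modelers and pharmacologists who want an open,
scriptable simulator for virtual-population trials of renally cleared
compounds.

## Model core

Renal clearance decomposes as

```
CLr = fu·GFR + CLsec ,      CLsec ≈ committed fraction · CLint,OAT1·fu
```

with filtration of unbound drug (`fu·GFR`) drawn from arterial plasma, and
secretion resolved mechanistically: basolateral OAT1 uptake into a proximal
tubular cell compartment (whole-organ `CLint,OAT1` IVIVE-scaled from in
vitro uptake via a relative expression factor, REF), apical MRP4 efflux and
passive diffusion, and tubular lumen flow into urine. A perpetrator inhibits
uptake competitively:

```
CLint,OAT1 -> CLint,OAT1 / (1 + Iu(t)/Ki) ,      Ki = 3.4 uM (unbound)
```

where `Iu(t)` is its time-resolved unbound concentration at the basolateral
membrane from its own whole-body simulation. CKD scales three quantities:
mean GFR, proximal-tubule cell number (proportional to the GFR decline;
intact nephron hypothesis) and OAT1 abundance (1.0 / 1.0 / 0.84 / 0.50 for
healthy / mild / moderate / severe). Distribution uses composition-based
tissue:plasma partition coefficients; bundled, calibrated parameter files
for adefovir (victim; oral dosing as the dipivoxil prodrug, entered as its
molar parent equivalent) and probenecid (perpetrator; saturable nonrenal
elimination) ship with the package. See `docs/methods.md` for the full
model description and every calibration anchor.

## Worked example

One subject of the crossover DDI design: 1.5 g oral probenecid given 2 h
before 10 mg oral adefovir-dipivoxil, versus the same subject without the
inhibitor.

```python
from renalpbpk import DosingRegimen, convert_prodrug_dose, pk_summary
from renalpbpk.ddi import simulate_ddi_subject
from renalpbpk.population import (japanese_population, sample_subject,
                                  subject_rng, MAEDA_SAMPLING_H)
from renalpbpk.workflows import bundled_drug

adefovir = bundled_drug("adefovir")
probenecid = bundled_drug("probenecid")
subject = sample_subject(japanese_population(), subject_rng(1, 0, 0), sex="M")

dose = convert_prodrug_dose(10.0, 273.19, 501.47)      # -> 5.45 mg adefovir
victim = DosingRegimen.single_oral(dose, start_h=2.0)  # 2 h after probenecid
perp = DosingRegimen.single_oral(1500.0, start_h=0.0)
sampling = [2.0 + t for t in MAEDA_SAMPLING_H]

pair = simulate_ddi_subject(adefovir, probenecid, subject, victim, perp,
                            t_end_h=12.0, sampling_times_h=sampling)
control = pk_summary(pair.control, dose_time_h=2.0, auc_window_h=8.0)
ddi = pk_summary(pair.ddi, dose_time_h=2.0, auc_window_h=8.0)
```

Output (printing the summaries as in the snippet above):

```
parent-equivalent dose : 5.45 mg
control  Cmax  14.7 ng/mL  AUC0-8h   96.7 ng.h/mL  CLr 0.193 L/h/kg
with prb Cmax  22.6 ng/mL  AUC0-8h  146.7 ng.h/mL  CLr 0.099 L/h/kg
ratios   CmaxR 1.54  AUCR 1.52  CLrR 0.51
```

Probenecid halves this subject's renal clearance — secretion is nearly
abolished, leaving filtration (`fu·GFR ≈ 0.10 L/h/kg`) — which raises the
0-8 h exposure about 1.5-fold. Population means over the full crossover
design (40 trials of 6 subjects) are produced by
`renalpbpk.workflows.run_ddi_experiment`.

The three study workflows are also exposed on the command line:

```
renalpbpk verify-healthy --seed 1 --out out/healthy
renalpbpk ddi           --seed 1 --out out/ddi
renalpbpk verify-ckd    --seed 1 --out out/ckd
renalpbpk drug validate src/renalpbpk/data/adefovir.yaml
```

Each writes `report.json` (every comparison with its predicted/observed
ratio and Guest / 1.5-fold criterion flags) plus summary tables, and exits
nonzero if any comparison fails its criterion.

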