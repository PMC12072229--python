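# Methods

`renalpbpk` simulates the plasma and urine kinetics of renally secreted
drugs with a whole-body physiologically-based pharmacokinetic (PBPK) model
whose kidney is resolved mechanistically, couples a victim and a perpetrator
through competitive inhibition of basolateral uptake, and scales the kidney
physiology for chronic kidney disease (CKD). The bundled application is the
OAT1 clinical probe adefovir (dosed orally as its dipivoxil prodrug) with
probenecid as the OAT1/3 inhibitor.

## Whole-body model

The body is a set of perfusion-limited tissues (adipose, bone, brain, gut,
heart, liver, muscle, skin, spleen, pancreas, rest-of-body) in parallel
between an arterial and a venous blood pool, with the lung in series
carrying cardiac output. All tissues are perfused directly from the arterial
pool: neither bundled compound has hepatic extraction, so a portal-vein
series arrangement could not change any reported quantity and is omitted.
Amounts are in mg, flows and clearances in L/h; plasma concentration is the
venous blood concentration divided by the blood:plasma ratio, matching
clinical venous sampling. Oral dosing uses a first-order depot with rate
constant `ka`, absorbed fraction `Fa`, and optional lag; a single rate
constant deliberately lumps intestinal absorption of the prodrug with its
rapid hydrolysis, so no prodrug species circulates and the dose is entered
as its molar parent equivalent (10 mg adefovir-dipivoxil = 5.45 mg
adefovir). The unabsorbed fraction and nonrenally eliminated drug flow into
explicit accumulator compartments, so total drug is conserved exactly and
the integrator's mass-balance error (assertion threshold 1e-6 relative) is a
direct quality measure.

Tissue-to-plasma partition coefficients are predicted from tissue
composition: ionization-weighted partitioning into extra- and intracellular
water, neutral-lipid and phospholipid partitioning of the unionized species,
extracellular albumin binding for acids/neutrals/ampholytes (with the
plasma-lipid correction inside the albumin association term carrying the
same unionized-fraction factor as the tissue lipid term), and acidic
phospholipid association for moderate-to-strong bases with the association
constant back-calculated from red-cell partitioning. Adefovir is treated as
an ampholyte dominated by its phosphonate ionizations (pKa 2.0 and 6.8) and
therefore handled on the net-acid branch. A global multiplier `kp_scalar`
absorbs transporter-mediated distribution the composition model cannot see;
it is calibrated once against the steady-state distribution volume (below).

## Mechanistic kidney

The kidney is replaced by a proximal-tubule unit: a renal vascular
compartment fed by renal blood flow; glomerular filtration of unbound drug
at `fu * GFR` drawn from the *arterial* plasma (the glomerulus filters
arterial blood — this also makes the filtration-only limit exact rather
than flow-damped); OAT1-mediated uptake of unbound drug from the renal
vascular plasma into a single proximal tubular cell (PTC) compartment;
MRP4-mediated apical efflux and bidirectional passive diffusion at both
membranes; three lumen segments in series whose fluid flow falls
geometrically from GFR to a urine flow of 1.4 mL/min (water reabsorption
concentrates the drug; no drug reabsorption, appropriate for a polar anion
with near-complete urinary recovery); and a cumulative urine compartment.
With basolateral uptake rate-determining and no reabsorption, steady-state
renal clearance is insensitive to the lumen segmentation, which is why three
segments suffice.

Transporter clearances are IVIVE-scaled from in vitro values
(uL/min/1e6 cells) by PTC cellularity (60e6 cells/g kidney), kidney mass
(300 g at 70 kg, scaled with weight), and — for OAT1 only — a relative
expression factor (REF = 2.0) and the subject's OAT1 relative abundance.
MRP4 efflux uses the reported 1.0 uL/min/1e6 PTC. PTC volume uses a
1.2 pL single-cell volume.

Competitive inhibition divides the OAT1 uptake clearance by
`1 + Iu(t)/Ki`, with `Ki = 3.4 uM` (unbound, biomarker-informed) and `Iu`
the perpetrator's unbound concentration in the renal vascular compartment of
its own simulation (basolateral exposure; for a perfusion-limited
perpetrator this is nearly unbound systemic plasma). The perpetrator is
simulated first and its exposure enters the victim's right-hand side through
a monotone cubic interpolant. Inhibition touches neither MRP4 nor passive
diffusion nor filtration.

## Numerics

The ODE system (23 states) is integrated segment-wise between dose events
with LSODA, relative tolerance 1e-8 and absolute tolerance 1e-10 mg, using
an analytic Jacobian (constant except the inhibition-scaled uptake entries
and the Michaelis-Menten venous term). Output is the union of a uniform
0.05-h grid, the study sampling times, and all dose boundaries. Negative
states within ~100x the absolute tolerance are clamped to zero; larger
negatives raise. Mass balance is asserted at 1e-6 relative. NCA uses the
linear-up/log-down trapezoid on the study sampling times (sparse clinical
grids by design); AUC(0-inf) extrapolates from a log-linear fit to the last
three positive samples. Renal clearance is Ae/AUC over the analysis window;
secretion clearance is the subtraction CLr − fu·GFR and is reported even
when negative. Clearance *calibrations* use a 0.5-h IV infusion and the
dense output grid, because a true bolus has no finite t=0 concentration for
the trapezoid and sparse-grid bolus NCA overestimates CLr by ~7%.

## Calibration of the bundled fixtures

Adefovir (`data/adefovir.yaml`, written by `scripts/calibrate_adefovir.py`):

* `kp_scalar = 1.745` — analytic solution so the composition-based Vss is
  0.39 L/kg (the reference prediction; observed 0.42 L/kg).
* in vitro OAT1 CLint `= 7.264 uL/min/1e6` (REF 2.0 fixed) — root-found so
  the mean healthy subject's renal clearance after 1.0 mg/kg IV is
  16.8 L/h. This leaves secretion at 62% of CLr and filtration at 38%,
  matching the ~60/40 split reported for adefovir. Passive diffusion is
  fixed at 0.15 uL/min/1e6 per membrane, small enough that the
  complete-inhibition limit collapses secretion to <2% of control.
* `ka = 0.137 /h` — root-found so the mean Japanese subject's control-phase
  profile shape Cmax/AUC(0-8h) equals the reported predicted 16.2/105 per
  hour on the sparse crossover grid. This stands in for the oral
  concentration-time data the original absorption optimization used, and
  independently reproduces the reported severe-CKD Cmax fold (2.6).
* Nonrenal clearance is zero (up to 98% of an IV dose is recovered in
  urine); `Fa = 0.47`.

Probenecid (`data/probenecid.yaml`, by `scripts/calibrate_probenecid.py`):
fu 0.10, monoprotic acid pKa 3.3, logP 3.21, B:P 0.6, `ka 0.8/h` (tmax
~2.8 h, clinical range 2-4 h), Fa 1.0, saturable nonrenal elimination with
Km fixed at 25 mg/L. `kp_scalar` (0.663) and Vmax (16.8 mg/h) are solved
jointly so that (i) unbound Cmax after 0.5 g oral equals 5.1 x Ki in the
mean Japanese male — the biomarker-informed exposure anchor — and (ii) the
apparent terminal half-life at 0.5 g is 4.8 h. Exposure then rises more
than dose-proportionally (dose-normalized AUC 1.02 -> 1.20 over
0.5-1.5 g), as observed clinically.

## Populations and trials

Subjects are drawn deterministically per `(seed, trial, subject)` from
counter-based streams, so trial parallelism or execution order cannot change
results. Demographics: weight log-normal (mean 75 kg White, 65 kg Japanese,
63 kg Chinese; CV 12%; females x0.85), age uniform in the design range, GFR
log-normal (healthy mean 110 mL/min, CV 15%). Ethnicities differ only by
body weight — no inter-ethnic difference in OAT1 activity is modeled.
Inter-individual variability is log-normal with CV 30% on OAT1 CLint, 25%
on ka and 20% on kp_scalar — typical PBPK defaults that reproduce the
reported population SD magnitudes. Volumes scale linearly and flows
allometrically (power 0.75) with weight. Creatinine clearance is treated as
equal to GFR for staging (half-open bins: severe [0,30), moderate [30,50),
mild [50,80], healthy (80,inf)).

CKD stages modify exactly three things: the mean GFR (65/40/25 mL/min for
mild/moderate/severe; bin midpoints), PTC number per gram scaled by the
ratio of stage mean GFR to healthy mean GFR (intact nephron hypothesis;
passive and MRP4 clearances scale with cellularity too), and OAT1 relative
abundance 1.0/1.0/0.84/0.50 for healthy/mild/moderate/severe — the
additional decline of OAT1 activity beyond GFR in later stages. Severe-CKD
secretion capacity is therefore (25/110) x 0.50 = 0.114 of healthy.

Study designs: the crossover DDI uses 40 trials of 6 Japanese men aged
20-31, probenecid 2 h before 10 mg adefovir-dipivoxil, sampling
0/0.5/1/1.5/2/3/4/6/8 h, AUC over 0-8 h; the generic design uses 10 trials
of 20 subjects (equal sexes, 20-50 y) with 0-48 h sampling; the CKD
verification mirrors the renal-impairment reference study with 30 trials of
8/8/8/9 subjects across stages (per-stage counts are an assumption; only the
33-subject total is reported). For the generic/CKD workflow "AUC" is NCA
AUC(0-inf) on the 0-48 h grid — total exposure, consistent with the
reference AUC arithmetic — while the crossover reports AUC(0-8h) as in the
source study. Crossover ratios are arithmetic means of within-subject
ratios (control and DDI phases share the identical subject draw); summary
tables are arithmetic mean ± SD. Multiple-dose arms run four once-daily
doses (accumulation is complete by dose two at these half-lives) and
analyze the final interval as steady state.

## Synthetic observed data

`synthetic.generate_observed_study` overlays the simulated truth with
proportional log-normal residual error (default CV 15%, median-unbiased)
and censors below an LLOQ of 0.5 ng/mL (values dropped, never clamped).
Urine is collected over 0-4/4-8/8-24 h. Summary tables are always computed
from the noisy records themselves. The bundled
`observed_summaries_synthetic.csv` (29 AUC, 22 Cmax, 8 CLr measurements
across nine study arms) was generated this way with 12% noise and clearly
labelled: verification against it is a null check of the whole pipeline
(expected R_pred/obs ~ 1), not a reproduction of historical measurements.
What passing these tests shows is that the pipeline is internally unbiased
at clinical sampling density and noise; what they cannot show is fidelity
to features the generator lacks — absorption variability beyond a
log-normal ka, time-varying residual error, dropout, or assay drift.

## Design choices that were genuinely open

* Washout between crossover phases is not simulated; phases are independent
  simulations sharing the subject draw (adefovir's half-life makes 7-day
  carryover negligible).
* The perpetrator's driving concentration is renal-vascular unbound rather
  than systemic unbound plasma; for probenecid the difference is <1%.
* Ratio summaries are means of within-subject ratios, not ratios of means
  (differences <3% at these variabilities).
* The Guest criterion uses delta = 1.25; the 1.5-fold criterion uses the
  printed lower bound 0.67 exactly (not 1/1.5).
* The one-compartment reduction used as an integrator oracle is obtained by
  scaling all flows x2000, collapsing the body to a single well-mixed
  volume.

## Known limitations

* The DDI ratios for sustained inhibition (1.0 g probenecid given
  simultaneously, full-AUC window) run ~0.2 above the reference model's
  predictions (e.g. healthy AUCR ~1.93 vs 1.73). The reference's
  renal-clearance ratios imply an effective average inhibitor pressure of
  only ~0.3-0.4x its unbound-Cmax anchor, a buffering its proprietary
  multi-segment kidney may produce but a single well-stirred peritubular
  compartment does not. The staggered 0-8 h crossover ratios are much less
  sensitive to this and agree within 0.11.
* Plasma-protein-binding changes, absorption changes and nonrenal-clearance
  changes in CKD are not modeled; only GFR, PTC number and OAT1 abundance
  carry the disease effect.
* No transporter saturation (linear victim kinetics), no OAT3 pathway for
  the victim, no passive tubular reabsorption, no enterohepatic
  recirculation.
* Problem sizes in the test suite are the package's own choices for a
  desk-scale reproduction: the acceptance designs (240 and 200 subjects)
  match the source study layouts; unit tests use smaller draws.
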