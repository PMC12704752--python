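# Methods

## The biological problem

In a mouse preovulatory follicle the oocyte is held in meiotic prophase
by a high cytosolic cAMP concentration (~700 nM). The oocyte makes this
cAMP itself (constitutive GPR3 / Gs signaling), but hydrolysis by the
oocyte phosphodiesterase PDE3A is held in check by cGMP, which diffuses
in from the surrounding granulosa cells through gap junctions and acts
as a competitive PDE3A inhibitor. The granulosa cGMP is produced by the
NPR2 guanylyl cyclase (agonist: C-type natriuretic peptide, CNP).
Luteinizing hormone (LH), acting only on receptors in the outer mural
granulosa layer, sets off a chain that ends with oocyte cAMP falling
several-fold and meiosis resuming: granulosa cAMP rises and spreads
inward by junctional diffusion; NPR2 is dephosphorylated and
inactivated (and PDE5A slightly activated), collapsing granulosa cGMP;
oocyte cGMP drains outward into the much larger granulosa volume;
PDE3A, disinhibited, hydrolyzes oocyte cAMP; and a transient closure of
the Cx43 junctions between granulosa cells cuts the cAMP resupply to
the oocyte during the critical window. This package turns that verbal
model into a quantitative simulator, plus the ratiometric FRET imaging
pipeline used to measure such dynamics, and a synthetic two-channel
time-lapse generator that lets the whole measurement chain be validated
closed-loop without any microscope.

## Model structure

Three well-mixed compartments — mural granulosa (m), cumulus (c),
oocyte (o) — each carry cAMP (A) and cGMP (G) concentrations in nM;
time is in minutes with LH at t = 0. Volumes come from the geometry of
a cultured follicle flattened to a 200-µm disc (~340 µm diameter,
antral fraction 0.15, 75-µm oocyte, 25-µm cumulus shell); with the
defaults V_m : V_c : V_o ≈ 65 : 3.6 : 1, which is what makes the
granulosa an effective sink for oocyte cGMP.

State equations:

    dA_m/dt = k_FSH + k_LH·λ(t) − k_degA_g·A_m − J^A_mc/V_m
    dA_c/dt = k_FSH − k_degA_g·A_c + J^A_mc/V_c − J^A_co/V_c
    dA_o/dt = k_GPR3 − Vmax3·A_o/(Km3·(1+G_o/Ki3)+A_o) + J^A_co/V_o
    dG_m/dt = V_NPR2·a(t) − (k5_basal+dk5_LH·θ5(t))·G_m − J^G_mc/V_m
    dG_c/dt = V_NPR2·a(t) − (k5_basal+dk5_LH·θ5(t))·G_c + J^G_mc/V_c − J^G_co/V_c
    dG_o/dt = −k_degG_o·G_o + J^G_co/V_o

with amount fluxes J_mc = P_mc·d(t)·ε_mc·(X_m − X_c) and
J_co = P_co·ε_co·(X_c − X_o). Dividing an amount flux by the receiving
volume conserves amount exactly across unequal compartments.

Time courses (all phenomenological, anchored to measured landmarks):

- LH receptor activation λ(t) = 1 − exp(−t/τ_LH) for t ≥ 0. A smooth
  onset rather than a step, so the 2.9-min mural half-rise is a fitted
  quantity, not a discretization artifact.
- PDE5A activation θ5(t), same form with τ_PDE5 (zero in the
  Pde5a-S92A genotype).
- NPR2 activity a(t) = φ(t)·ψ(t). φ is the fast
  dephosphorylation/inactivation component, relaxing from 1 to φ_min
  with time constant τ_dephos (identically 1 in Npr2-7E). ψ tracks the
  slow post-LH loss of follicular CNP, modeled as
  exp(−(t/τ_CNP)^h) (identically 1 when CNP is clamped by exogenous
  peptide). The shape exponent h is fitted and comes out below 1
  (stretched exponential): fast initial loss with a long weak tail.
  That tail is what lets the model reproduce three landmarks at once —
  the mutant mural cGMP minimum near 3 h, the wild-type oocyte cAMP
  minimum near 3 h, and the AG1478 oocyte trace reaching the wild-type
  minimum only near 5 h. Because a gap-junction-opened follicle always
  has at least as much cAMP resupply as the wild type, its trace is
  bounded below by the wild-type trace; it can only reach the
  wild-type minimum after the wild-type recording window closes, which
  requires exactly this kind of slowly completing relief of PDE3A
  inhibition.
- Cx43 permeability d(t): two C1 smoothstep ramps, exactly 1 up to
  dip_onset (20 min), minimum dip_depth at dip_min_time (60 min),
  exactly 1 again from dip_recovery_time (300 min). AG1478 forces
  d ≡ 1. Cx37 (cumulus–oocyte) permeability is constant over the
  modeled 5-h window.
- Carbenoxolone: static residual permeability factors ε_mc, ε_co,
  fitted so the cumulus ratio response is ~30% of control and the
  oocyte response is nearly abolished.

The pre-LH state is the exact fixed point of the system with all
LH-driven terms off, found by Newton iteration from the analytic
closed form (residual < 1e−8 nM/min enforced). Integration uses LSODA
with rtol 1e−8 / atol 1e−9 nM and a 5-min step cap (so the solver
cannot step over the dip), interpolated to the requested output grid.
A fixed-step explicit-Euler oracle at dt = 0.001 min agrees with the
adaptive solution to <0.5% and backstops the solver in the test suite.

## Parameter calibration

The published record pins concentrations and times, not rate
constants, so the defaults are calibrated: bounded least squares on
log-parameters (17 effective degrees of freedom) against the twelve
registered landmarks plus trace-shape guards (oocyte cAMP ≈170 nM at
180 min, ≥~172 nM over 220–300 min so the minimum stays at ~3 h, a
soft mid-decline target at 120 min, and near-complete carbenoxolone
block of the oocyte response). Three quantities are eliminated
analytically: k_FSH = 700·k_degA_g and k_GPR3 from the requirement
that the basal state sit exactly at the measured 700 nM in all
compartments, and the absolute granulosa cGMP scale, which is not
identifiable (the cGMP dynamics are linear, so only the ratio
G_o/Ki3 enters anywhere); it is fixed at 1500 nM and Ki3 is derived
from the fitted inhibition strength. `scripts/fit_defaults.py`
reproduces the calibration; the shipped defaults in
`follicle_cnd.parameters` are its converged output.

Consequences worth flagging: Km3 (~60 nM) and Ki3 (<1 nM) are
compartment-averaged effective constants that absorb unknown scale
factors (true oocyte cGMP concentration, PDE3A abundance); they should
not be read as in vitro enzyme constants. The relative contributions
of PDE3A disinhibition versus junction closure to the depth of the
oocyte cAMP minimum are not separable from the printed data, so
dip_depth is constrained only jointly with the enzyme parameters.

## Metric definitions

All landmark metrics run on sampled traces with linear interpolation
between samples (the measurements report sub-frame precision, e.g.
2.9 ± 0.1 min). Baseline = mean over all pre-LH frames (≥5 required).
Time-to-50%-of-peak: first upward crossing of baseline + 0.5·(peak −
baseline) after LH. Time-to-25%-decline: first downward crossing of
baseline − 0.25·(baseline − post-LH minimum). "Time to reach the
minimum level" is operationalized as completing 95% of the
baseline-to-minimum excursion (threshold = min + 0.05·(baseline −
min)); defining it as "within 5% of the minimum value" degenerates
when the minimum approaches zero, as mural cGMP does. NEBD in
simulated traces: first time oocyte cAMP stays below 185 nM for 15
min (threshold and hold configurable; chosen so the wild-type default
lands in the observed 2–4 h window).

## Synthetic imaging and its limits

The generator renders concentric regions (nucleus, oocyte, cumulus,
granulosa with dark antral patches and an outer mural band, dim static
theca rim) on a 512×512 16-bit frame at 0.8 µm/pixel, on the
experimental schedule (≥10 min baseline, 1-min frames for the first
hour, 5-min after). Region brightness = expression level ×
signal-to-background (3–10×) × per-channel autofluorescence; the
CFP/YFP split is chosen so the ideally corrected ratio equals the
sensor calibration exactly (CFP = B·R/(1+R), YFP = B/(1+R)); YFP then
receives α = 0.23 of the CFP sensor signal as spectral bleed-through;
Poisson shot noise, Gaussian read noise (2% of intensity), and integer
translational jitter are applied last. NEBD is an instantaneous
nuclear fill (no transition kinetics are reported). The sensors are
modeled as Hill curves (defaults: EC50 1000 nM for cAMPFIRE-M, 500 nM
for cGi500, n = 1, ratio span 1–3), whose mid-range is log-linear to
<2% — the regime the calibration measurements rely on.

What the generator does not emulate: photobleaching and sensor
maturation, 3-D sectioning/PSF blur, follicle deformation (only rigid
translation), the sometimes-observed cumulus cAMP oscillations, and
theca dynamics. Closed-loop tests therefore demonstrate that the
pipeline is unbiased under the modeled artifacts (bleed-through,
noise, jitter, 5-fold expression variation), not that it is robust to
everything a real microscope produces.

## Analysis pipeline choices

Registration is translation-only phase correlation on the
summed-channel image against the first frame, applied identically to
both channels; masks are static afterwards (the experimental practice
of manually nudging ROIs has no algorithmic definition). Correction
order is fixed — background subtraction first, then spectral overlap —
because α applies to sensor signal, not autofluorescence; a regression
test pins the order. Per-region backgrounds come either from the
stack's own extra-follicular ROI or from five "uninjected"
(autofluorescence-only) synthetic follicles, mirroring the
experimental n = 5. Ratios where corrected YFP falls below a floor
(default 10 counts) are flagged, not raised. NEBD detection uses
nuclear/cytoplasm mean-intensity thresholds 0.7 (rise) after staying
below 0.4, both configurable — these two numbers are conventions of
this package, not measured values.

## Scenario layer

Named presets map to perturbation-flag combinations (wild_type,
npr2_7E_pde5a_S92A, ag1478, carbenoxolone, cnp_clamp — the CNP-clamp
preset includes the phosphomutant background, matching the experiment
that motivated it). Cohorts larger than one follicle draw lognormal
(CV 10%) per-follicle factors on k_GPR3 and V_NPR2; all anchor checks
run on single deterministic traces with jitter off. Anchor tolerances
follow the precision markers of the source values: ±15% for "~"
figures, ±10% for mean ± SEM figures.

## Problem sizes

Default simulations cover −10 to 300 min at 0.25-min output steps
(denser than the 1-min acquisition so interpolated crossing times are
stable to <0.5 min; a sampling-stability test verifies this).
Rendering tests use 160×160 frames at 2.5 µm/pixel — the geometry,
artifacts and pipeline are identical, only the pixel count differs —
while the default scene is full 512×512.

## Known limitations

- The late cumulus cAMP plateau is capped near ~2,000 nM: the
  mural-to-cumulus coupling strength that reproduces the 5.5-min
  cumulus half-rise is too weak for the cumulus to rejoin the mural
  ~3,400 nM level by 5 h. The measured late re-rise is attributed to
  gradual reopening of mural-cumulus junctions, which the model's
  single dip-and-recover permeability course only partially captures.
- The cumulus transient dip and re-rise emerges from the fitted model
  (drainage into the disinhibited oocyte while Cx43 is closed, then
  re-equilibration) as a prediction; its depth is not constrained by
  any printed number.
- Everything downstream of oocyte cAMP (PKA substrates, IP3 receptor
  maturation, the actual mechanics of NEBD) is outside the model; NEBD
  is a threshold readout.
- Effective enzyme constants, as noted above; and the absolute Cx43 /
  Cx37 permeabilities are constrained only through the volume-scaled
  exchange rates.
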