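# Methods

## Scope and data flow

The package quantifies drug removal by hemodialysis (HD) in a
miniaturized rat model and extrapolates it to patients. The pipeline
is: per-session adequacy metrics (dialyzer clearance, Kt/V) →
dialysate-recovery removal rate with first-order session-length
extrapolation → protein binding (ultrafiltration) and steady-state Vd
(non-compartmental analysis) → cross-species regression of human
dialyzability on the rat measurements. A two-compartment simulator
stands in for the animal experiments in tests.

## Dialysis metrics

**Dialyzer clearance.** `CL = (Ca − Cv)/Ca · Q_B · (1 − Hct)` (mL/min),
with inlet/outlet concentrations Ca, Cv, blood flow Q_B and hematocrit
Hct as a fraction in [0, 1]. `(1 − Hct)` converts blood flow to the
plasma flow actually cleared. The outlet concentration is taken as
already corrected for hemoconcentration by ultrafiltration; the raw
correction is an assay-side step with no standard closed form, so it is
deliberately out of scope and the API documents `c_outlet` as
pre-adjusted. Negative clearance (Cv > Ca) is a warning, not an error:
near zero extraction, sampling noise can invert the gradient.

**Kt/V.** Second-generation Daugirdas single-pool formula,
`−ln(R − 0.008·Td) + (4 − 3.5·R)·UFV/BW`, `R = BUN_post/BUN_pre`, `Td`
in hours (the 0.008 urea-generation term is per hour). `UFV/BW` is
dimensionless provided the two share a unit system; the session record
declares the pair (`L_kg`, `mL_g`, `g_g`, `kg_kg`) and validates it.
Equilibrated Kt/V and double-pool urea kinetics are non-goals.

**Removal rate and extrapolation.** Removal is percent of dose
recovered in pooled dialysate; values above 100% are mass-balance
violations and raise. The 2 h → 4 h extrapolation treats removal as
mono-exponential depletion: `R(t) = 100·(1 − (1 − R₀/100)^(t/t₀))`,
implemented with `expm1`/`log1p` so precision survives near both ends.
Exposed at arbitrary `(t_measured, t_target)` with 4 h as the default
target. Note the float64 limit: once a removal exceeds ~99.99% the
surviving fraction is no longer representable on the percent scale, so
the round-trip identity `R(t₂→t₁)∘R(t₁→t₂) = id` holds to 1e-9 relative
only below that saturation zone (the property tests encode exactly
this).

## Non-compartmental analysis

Linear trapezoid on the observed grid (the default; log-down trapezoid
available via `method="log"`, exact for mono-exponential decline within
a segment), plus the standard tail terms `C_last/λz` and
`t_last·C_last/λz + C_last/λz²`. λz is OLS on ln(C) over the last
`n_terminal` positive points (default 3, configurable; automatic
best-fit selection is out of scope). A non-declining tail raises rather
than extrapolating. `MRT = AUMC/AUC − T_inf/2` applies the
constant-rate-infusion correction; `V_ss = CL·MRT` per kilogram of the
supplied body weight, no allometric scaling. Compartmental fitting to
data is deliberately absent — the simulator generates compartmental
curves, but parameters are never estimated from data by compartment
models.

## Cross-species regression

Candidate predictors of `DD_human` (percent removed in a 4-h clinical
session): the rat 4-h removal rate alone (Eq 1), multiplied by the
human/rat unbound-percentage ratio `(100−PBR_h)/(100−PBR_r)` (Eq 2), or
with a second additive predictor `Vd_h/Vd_r` (Eq 3) or
`(fu/Vd)_h/(fu/Vd)_r` (Eq 4). Fits are ordinary least squares with
intercept (statsmodels under the hood; tests cross-check coefficients,
r², adjusted r² and the overall F p-value against a closed-form
normal-equation oracle). Model selection maximizes
`adj r² = 1 − (1 − r²)(n−1)/(n−p−1)`; ties break to the lower equation
id. Design-matrix construction requires at least 4 drugs for
one-predictor and 5 for two-predictor models.

**Range resolution.** Literature human dialyzability and Vd are often
printed as ranges. The regression needs point values, and the source
tables do not say which point entered the published fits. The package
resolves `DD_human` ranges to their **upper** bound and human Vd ranges
to their **lower** bound by default: this is the convention under which
the packaged table reproduces the published statistics — adjusted r² of
0.812 / 0.935 / 0.749 / 0.752 for Eqs 1–4, slopes 1.263 and 1.225, Eq 1
overall p = 0.009, and the ordering Eq2 > Eq1 > Eq4 > Eq3 — to within
±0.005, the reproduction limit imposed by table-rounded inputs. Both
conventions are configurable (`upper|mid|lower`) and a different choice
changes Eqs 3–4 noticeably, so the default is flagged here as inferred
from numerical reproduction, not stated by the source. Intercepts and
the small a2 coefficients are *not* reproducible from rounded table
inputs (the published fits evidently used unrounded per-animal data)
and are reported but not checked.

**The 4-h column.** The packaged 4-h rat removal rates are the
published per-animal-averaged values. Group-level application of the
extrapolation formula to the 2-h means agrees exactly at printed
precision for three drugs and to 0.1 (amikacin) / 0.3 (valproate)
percentage points for the two where per-animal averaging of a concave
map differs from the map of the average. Aprindine, undetected in
dialysate, is encoded as exactly 0% in both species.

No uncertainty propagation from the printed ± SD into the regression
(point fits only), and no cross-validation or information-criterion
selection — adjusted r² is the published selection rule.

## Simulator

Two compartments with amounts `A1 = C1·Vc`, `A2 = C2·Vp`:

    dC1/dt = [rate_in(t) − Q·(C1 − C2) − (cl_HD(t) + cl_nr)·fu·C1]/Vc
    dC2/dt = Q·(C1 − C2)/Vp

`cl_HD(t)` equals `cl_dialyzer` inside scheduled windows, 0 outside.
Renal clearance is hard-coded to zero (the animal model is bilaterally
nephrectomized); nonrenal clearance defaults to 0 so mass balance
closes on the dialysate alone. The dialyzer acts on the *unbound*
central concentration (`cl·fu·C1`) — the simplest mechanism consistent
with protein binding limiting dialyzability; it is a modelling choice
of this package, not an experimentally established mechanism.

Integration is segment-wise between infusion and window boundaries
(LSODA, rtol 1e-10, atol 1e-12), so clearance discontinuities fall on
segment edges and are never smeared across an adaptive step. The state
carries cumulative dialysate and nonrenal masses; mass balance closes
to ≤1e-6 relative at every output point and is asserted in tests. In
the one-compartment limit the simulated removal matches the closed form
`100·(1 − e^(−cl·fu·t/V))` to 1e-6, which also makes the first-order
session extrapolation exact; with a peripheral compartment and slow
redistribution the extrapolation overestimates true 4-h removal, and
the simulator reproduces the post-dialysis rebound (plasma rising after
the dialyzer stops) seen clinically for vancomycin.

Cohort generation uses one `numpy` Generator per cohort seeded by a
single integer; inter-subject variability perturbs volumes and
clearances lognormally (mean-preserving, `sigma² = ln(1+CV²)`), and
measurement noise is multiplicative lognormal per observation. Fixed
seed ⇒ byte-identical output.

**What the simulator does and does not emulate.** It produces
bi-exponential plasma curves under constant-rate infusion with
intermittent dialysis, cumulative dialysate mass and the rebound — the
phenomenology needed to exercise the pipeline end to end. It does not
model dialyzer mass transfer (KoA, countercurrent), BUN/electrolyte
physiology, nonlinear binding, or time-varying hematocrit, so passing
tests demonstrate internal consistency of the analysis chain, not
fidelity to any particular animal dataset.

## Problem sizes and numerical choices

Default test problem sizes: dense NCA grids of ~10⁴ points over 10–40
half-life units (trapezoid error well under the 1% assertion levels);
simulator grids of 200–1200 points over 2–12 h; 200-seed parameter
recovery at n = 50 per regression. The group-mean Kt/V check uses the
published mean pre/post BUN (117 → 106 mg/dL over 2 h) and the 2.4-g
session weight loss as ultrafiltration volume, giving ≈0.120 — inside
the published per-animal 0.13 ± 0.06, which is the only comparison the
unpublished raw inputs allow.

## Known limitations

- Six drugs underlie the packaged regression; adjusted r² on n = 6 with
  up to two predictors is fragile, and the two-predictor fits are not
  significant (p ≈ 0.06). The selection outcome, not the coefficient
  values, is the robust result.
- The range-resolution convention is inferred (see above); users with
  better point estimates should supply their own table.
- The protein-binding adjustment assumes binding is linear and species
  difference in fu acts multiplicatively on removal.
- NCA terminal-fit point count is fixed, not data-driven.
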