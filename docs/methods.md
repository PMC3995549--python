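# Methods

This note documents the models, conventions and numerical choices behind
`hdpk`, and what its synthetic studies do and do not demonstrate.

## Data model and units

All observations live in long-format concentration–time records keyed by
(subject, analyte, matrix): analyte ∈ {parent, metabolite}, matrix ∈
{plasma, dialysate}. Time is hours since dosing; the dose is given at
t = 0, immediately after the end of a dialysis session, and the next
session sits at 44–48 h on the same clock (dialysate flow 500 mL/min,
blood flow 250 mL/min). Concentrations are ng/mL, doses mg; the 10⁶
mg→ng factor is applied only inside clearance formulas, so
CL/F = dose/AUC_last emerges in L/hr and CL_HD = R/AUC_HD in mL/hr.
Default assay limits are 0.2 ng/mL (parent) and 2 ng/mL (metabolite).

**BLOQ convention.** The source design reports quantification limits but
no censoring rule, so the package declares the dominant NCA convention:
records below the limit *before* the first quantifiable sample are set to
zero (absorption has not begun); embedded and trailing BLOQ records are
excluded, so AUC_last ends at the last quantifiable time. A profile with
no quantifiable record is flagged unusable rather than silently zeroed.
The rule is idempotent, which the property suite checks.

## Non-compartmental analysis

* AUC uses the linear trapezoidal rule only (the study protocol names no
  log-linear variant); window boundaries that fall between samples are
  linearly interpolated. AUC is exactly additive over adjacent windows
  and homogeneous of degree one in the concentrations.
* C_max/T_max are read directly off the profile; ties resolve to the
  earliest time.
* AUC_HD is the plasma AUC over the dialysis window; the recovery amount
  R integrates dialysate concentration × dialysate flow over the session.
* λ_z is fitted by log-linear least squares over every suffix of ≥3
  quantifiable points after (and excluding) T_max, keeping the window
  with the best adjusted R² — the common commercial-NCA default. The
  protocol never reports λ_z or half-lives; here it exists purely so
  superposition can extrapolate beyond the last sample, and `run_nca`
  tolerates its absence. That tolerance matters: under the default
  design the metabolite often peaks at the 44-h pre-dialysis sample,
  leaving only two later samples — exactly the situation where no
  terminal fit is possible and none is needed for a single-dose
  prediction over 0–72 h.
* Group summaries report mean (SD), T_max as median [min, max], and group
  clearances as means of per-subject ratios — *not* the ratio of group
  means. The two differ noticeably (dose/mean-AUC at the lowest pilot
  dose is ≈772 L/hr while the mean of per-subject CL/F is ≈554 L/hr in
  the reference data), and the per-subject mean is the reported
  convention.

## Dose-proportionality gate

Dose-normalized C_max and AUC_last are compared across dose groups with
the Kruskal–Wallis test (tie-corrected H, χ² p-value, via
`scipy.stats.kruskal`; the all-identical degenerate case is defined as
H = 0, p = 1). The decision rule is the power model: OLS of ln(value) on
ln(dose), pooling per-subject values across escalation periods
(4 subjects × 3 doses = 12 observations; period and subject effects are
deliberately *not* modeled — the reference analysis is a plain log-log
regression, and that simplicity is a documented limitation). The 95% CI
is β ± t₀.₉₇₅,ₙ₋₂·SE; a parameter passes when the closed interval
contains 1.0 (the boundary counts — the permissive reading of "includes
1.0"), and the study gate passes only if every gated parameter passes
(C_max and AUC_last for both analytes, plus the metabolite's AUC_HD).
With zero residual variance the CI degenerates to a vanishing interval
around β rather than NaN. The fit is closed-form and cross-checked
against `statsmodels` OLS in the test suite. Calibration: with a true
unit slope and log-normal noise the interval covers 1.0 at its nominal
95% rate (checked over 2,000 pilot-sized replicates).

A pipeline whose pilot fails the gate halts with a report; a
`--force-gate` override exists because a 12-observation pilot can fail by
chance, and the halt-versus-override policy is this package's own choice
(the source design never states what a failed gate would have triggered).

## Nonparametric superposition and dose selection

The single-dose reference profile, linearly interpolated inside its
observed range and extended beyond its last sample by
C(t_last)·exp(−λ_z·(t−t_last)), acts as a per-mg impulse response.
Assuming dose-linearity (which Step 1 just established),

    C_pred(t) = Σ_k (D_k / D_ref) · C_ref(t − t_k),

with terms zero before each dose time t_k. Profiles are evaluated on a
0.1-h grid augmented by every reference sample time shifted to every dose
event, which keeps the single-reference-dose case an exact identity and
bounds trapezoid discretization error well below reporting precision.

The default regimen template is a single dose observed over 0–72 h with
the dialysis session embedded in the reference profile; superposing a
profile measured under dialysis therefore assumes every dosing cycle
repeats the same dialysis schedule, and extrapolation with the metabolite
terminal slope ignores any post-dialysis rebound (unassessed in the
reference data; the simulator likewise omits it by default). For that
template the predicted curve reduces to AUC(D) = (D/D_ref)·AUC_ref; the
machinery stays general for repeated-dose templates, which are checked
against brute-force shifted summation and the steady-state geometric
series C₀/(1−e^(−λτ)).

The dose–exposure curve is built per subject, averaged across subjects at
each grid dose (the grid runs from the reference dose to 150 mg in
reference-dose steps), inverted at the target by piecewise-linear
monotone interpolation, and rounded **up** to the 5-mg increment
(ceiling mode, reverse-engineered from the reference study's 34.61→35 mg
step; only "rounded up" is stated there). Subjects whose reference
profile cannot support the template (e.g. no terminal phase where
extension is required) are excluded with a notice rather than aborting
the run. The reference study's own recommendation (34.61 mg) is *not*
reproducible from its printed summary (linear scaling of the printed mean
AUC gives ≈26.8 mg); its exact multiple-dose regimen and weighting were
never specified, so the template and aggregation are configuration here,
with no claim to match that figure.

## Validation metrics

Predictions are scored against observations at the observed quantifiable
times: MAPE, average fold error AFE = 10^mean(|log₁₀(pred/obs)|) and the
fraction of pairs within 2-fold (boundaries count). The reference report
offers only visual agreement; the automated thresholds used in the test
suite (AFE ≤ 1.3, ≥80% within 2-fold) are this package's conventions.
Because the validation cohort re-enrolls the low-dose subjects, the
pipeline compares *group-mean* observed profiles against the mean of
per-subject predictions; per-profile scoring is available directly via
`validate_prediction`.

## Synthetic study generator

Structure: gut → parent plasma → metabolite plasma, first-order
absorption and conversion, one-compartment disposition for both species,
metabolite clearance CL_m(t) = CL_m,inter + CL_HD·1{dialysis}, dialysate
concentration CL_HD·C_m/Q_d during sessions. Integration is piecewise
between the clearance discontinuities with LSODA at rtol 1e-9 and
dense output; the noiseless cascade without dialysis matches the
closed-form three-exponential (Bateman-type) solution to integrator
tolerance, and mass balance closes to ≲1e-5.

Default typical values — ka 1.5 /hr, F 1, fm 0.8 (the fraction of an
oral dose reaching the circulation as active metabolite), V_p 600 L,
CL_p 770 L/hr, V_m 15 L, CL_m,inter 0.03 L/hr (anuric: essentially no
elimination between sessions), CL_HD 10 L/hr, Q_d 500 mL/min — were
chosen once so that a 2.5-mg dose yields a metabolite AUC_last near
5,600 ng·hr/mL and C_max near 130 ng/mL, with the parent falling below
0.2 ng/mL after ~3–6 h. These are tuning targets, not a calibrated
digital twin: true parameter values for anuric patients are unpublished.
One deliberate deviation from the reference tables: their recovery-method
outputs (CL_HD of ~5–7 **mL**/hr, ~0.05% of dose dialyzed) are mutually
consistent but would put dialysate concentrations two orders of magnitude
below the stated quantification limit, contradicting the reported
dialysate measurements and the concern about post-dialysis rebound. The
simulator uses a physiologically defensible dialytic clearance
(10 L/hr ≈ 170 mL/min for a small water-soluble solute on a high-flux
membrane) so that dialysate profiles are quantifiable and the
intradialytic concentration drop is visible; its simulated "% excreted"
is correspondingly tens of percent. The recovery formulas themselves are
implemented exactly as defined and unit-tested against the printed
arithmetic.

Variability: log-normal between-subject CV 30% on (ka, V_p, CL_p, V_m,
CL_m,inter, CL_HD), proportional (log-normal) residual CV 15%, both
configurable per parameter; observations below the LLOQ are flagged BLOQ.
The saturable variant replaces parent elimination with
V_max·C/(k_m + C), V_max = CL_p·k_m, so k_m → ∞ recovers the linear
model exactly; at k_m = 2 ng/mL the parent AUC/dose rises across
2.5/5/10 mg and the gate fails on noiseless data, as intended.

What passing tests show — and what they do not: the generator shares the
one-compartment, log-normal, proportional-error assumptions with the
estimators built to analyze it, so end-to-end recovery (recommended dose
within 15% of the exposure target with 10 subjects; AFE ≤ 1.3)
demonstrates internal consistency of the method at the study's scale, not
accuracy on real patients with rebound kinetics, nonstationary dialysis
schedules, or model misspecification. The end-to-end accuracy check is
evaluated at the *exact* recommended dose against the enrolled cohort's
true exposure; the practical dose is by construction biased upward by up
to one rounding increment, a deliberate safety policy rather than an
estimation error.

## Problem sizes and determinism

Simulated studies use the reference design scale throughout: 4-subject
pilots, 10-subject low-dose/validation cohorts, the 12-point sampling
schedule (pre-dose plus 1–72 h, hourly dialysate during the session),
2,000 replicates for CI calibration, and 0.01-h grids for ground-truth
integrals. Every stochastic element flows from explicit integer seeds
(`numpy.random.default_rng`); the analysis pipeline itself contains no
randomness, so identical inputs produce byte-identical artifacts.
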