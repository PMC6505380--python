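# Methods

## Scope and data flow

The package analyses three kinds of input: sparse oral concentration–time
profiles (CSV, one sample per row), in vitro substrate–velocity assay tables,
and scalar interaction summaries (AUC ratios, fractions metabolized,
inhibitor potencies). The pipeline is NCA → group AUC ratio → static-DDI
algebra → cross-species translation, with the enzyme-kinetics module
supporting the in vitro side and the simulators providing ground-truth test
beds for all of it.

## Noncompartmental analysis

AUC to the last observation uses the linear trapezoid rule throughout.
Lin-log integration would weight the declining phase differently; linear is
the conservative default and all desk-scale reproductions in the test suite
derive from printed AUCs rather than re-integration, so the choice only
affects simulation studies, where it is accounted for in the tolerances.

The terminal rate constant λz comes from ordinary least squares of ln C on t
over candidate windows: the last k positive-concentration samples for k from
`min_points` (default 3) up to all samples strictly after T_max, C_max
excluded. The window maximizing adjusted R² wins; ties go to the larger
window; λz = −slope must be positive, otherwise the terminal phase is
undefined and AUC_inf, half-life and CL/F are reported as missing while
AUC_all stays valid. AUC_inf = AUC_all + C_last/λz with C_last the last
usable observed concentration — an observed terminal zero therefore adds no
tail. CL/F converts the dose to the mass unit of the concentrations, so
10 mg/kg over 76 h·µg/ml gives 10000/76 ≈ 132 ml/h per kg regardless of the
input unit.

BLQ policy (the underlying studies do not state one, so the package fixes a
standard convention): a below-quantification sample before the first
quantifiable one is imputed as zero at its nominal time; later BLQ samples
are dropped from both the AUC and the λz fit. C_max ties resolve to the
earliest time. Group AUC ratios are ratios of arithmetic means, which is
what reproduces printed group-level ratios (e.g. 2008/230 → 8.7).

## Static reverse-inhibition DDI model

AUCR = 1/[(1 − f_m) + f_m/(1 + [I]/K_i)] with its exact rearrangement for
[I]/K_i and the complete-inhibition limit f_m = 1 − 1/AUCR. Assumptions:
one enzyme, one reversible inhibitor, inhibitor exposure constant over the
victim profile, no mechanism-based inactivation or induction terms, no
gut-wall extraction. The feasibility ceiling AUCR < 1/(1 − f_m) is enforced
with a dedicated error; AUCR ≤ 1 is rejected as "no interaction" when
back-solving.

All computation is unrounded internally. `round_paper_style` provides the
conventional presentation (f_m to two decimals, [I]/K_i to the nearest
integer, AUCR to two decimals), and `translate_prediction` exposes a flag to
round the intermediate potency before the forward step, matching how such
chains are computed by hand. Both paths agree to well under 0.1 % here
(9.7345 rounded-intermediate vs 9.7300 carried unrounded).

## Species dose translation

Surface-area normalization with the standard regulatory Km factors (mouse 3,
rat 6, adult human 37 at 70 kg; the full small table ships in
`scaling.KM_TABLE`). HED = dose × Km_animal/Km_human; total human dose
multiplies by body weight and rounds to the nearest 10 mg by default (the
unrounded value is always returned alongside) — the increment that maps
198.6 → 200 mg and 170.3 → 170 mg. The conversion is linear in dose and
exactly invertible before rounding.

## Enzyme kinetics

Michaelis–Menten fits minimize squared residuals of V = Vmax·S/(Km + S) via
Levenberg–Marquardt (trust-region reflective with nonnegativity bounds);
default starts are Vmax₀ = max observed V and Km₀ = the substrate
concentration at half Vmax₀ by linear interpolation. Standard errors come
from the Gauss–Newton covariance at the optimum. Weighting is selectable:
unweighted (default, the common commercial-fitter default), 1/V, or 1/V²
for data whose error is a constant coefficient of variation.

Preparation comparison uses the extra-sum-of-squares F-test,
F = ((RSS_shared − RSS_sep)/Δdf)/(RSS_sep/df_sep) with df_sep = n − 4,
in two variants: fully shared (Km, Vmax), and shared Km with separate Vmax —
the scientifically interesting one when expression levels differ but
affinity should not. The test holds its nominal level only when the
weighting matches the error structure: under constant-CV noise the
variance spans the velocity range squared, and the unweighted variant
rejects far above nominal (≈0.12 at α = 0.05 in the calibration simulations)
while 1/V² weighting is nominal (≈0.05). Analyses of relative-error assay
data should therefore use `weighting="1/v2"`; the calibration property in
the test suite does.

Substrate depletion fits ln(C/C₀) against time by OLS; a non-negative slope
yields a "stable" verdict (mirroring a no-cofactor control) instead of a
half-life. Percent-of-control inhibition is the plain ratio ×100.

## Synthetic data

Profiles come from a one-compartment first-order absorption model,
C(t) = D·(F/V)·ka/(ka − ke)·(e^(−ke·t) − e^(−ka·t)), with the analytic
ka = ke limit, closed-form AUC₀₋∞ = D·(F/V)/ke, and flip-flop kinetics
permitted. Defaults emulate a typical probe-substrate study in mice:
10 mg/kg oral dose, V/F = 1000 ml/kg, ka = 3 h⁻¹, ke = 0.4 h⁻¹, and a sparse
8-point 0.25–24 h sampling grid.

Noise is multiplicative lognormal with log-scale mean zero
(median-unbiased) and σ = √ln(1 + CV²); concentrations stay positive by
construction. Inter-subject variability applies the same lognormal law to
each subject's ke and F/V. DDI cohorts scale the treated arm's ke by the
static-model clearance factor (1 − f_m) + f_m/(1 + [I]/K_i) (inhibition) or
(1 − f_m) + f_m·fold (induction), so the expected AUCR is analytic and the
whole chain can be tested for recovery. A single cohort seed expands into
per-subject substreams via `numpy.random.SeedSequence.spawn`, making every
generator bit-reproducible.

What the generator does not emulate: multi-compartment disposition,
enterohepatic recirculation, gut-wall first pass, nonlinear (saturable)
elimination, time-varying inhibitor exposure, and assay LOQ censoring.
Passing recovery tests therefore validate the estimators under the stated
model, not the model's adequacy for any particular real compound.

## Numerical choices and problem sizes

Recovery studies in the test suite use: noiseless one-compartment profiles
with 12 samples to 12 h for NCA calibration (λz within 2 %, AUC_inf within
5 %); 200 seeded cohort replicates at n = 8 per arm, 10 % residual and
inter-subject CV, on a 13-point grid extending to 96 h so the slowed treated
arm still spans several half-lives (median f_m recovered within 0.02,
median [I]/K_i within 15 % — the potency back-solve steepens near the
feasibility ceiling, which dominates that tolerance); 500 Michaelis–Menten
replicates at 5 % CV (median parameters within 5 %); 1000 F-test replicates
for the type-I calibration. Trapezoid discretization on sparse grids biases
AUC a few percent low; tests that check agreement with analytic integrals
either use the sparse design's stated tolerance or a dense grid to
demonstrate convergence.

## Known limitations

Single-enzyme, single-inhibitor static model only; no PBPK or
time-dependent inhibition. NCA offers no partial/urinary AUC metrics or
bioequivalence statistics. The Km-factor table covers the common laboratory
species, not pediatric or exotic scaling. The F-test compares exactly two
preparations; multi-group comparisons need repeated pairwise tests with the
user's own multiplicity control.
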