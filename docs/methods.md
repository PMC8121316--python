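# Methods

## Physical model

A GUV of radius r₀ grown in sucrose buffer and transferred to a
lower-osmolarity glucose bath swells until the elastic stretching of the
membrane balances the osmotic driving force. The tension at swelling
equilibrium follows from the force balance

    σ_os = K_A R T ΔC⁰ / ( 2K_A/r₀ + (R T/2)(3 C_out − ΔC⁰) )      (full)
        ≈ 2 K_A ΔC⁰ / (3 C_out)                                     (approx)

with the area compressibility modulus K_A (N/m), gas constant R,
temperature T, initial inside-minus-outside osmolarity difference ΔC⁰ and
external osmolarity C_out (both in mol/m³ ≡ mOsm/L). At protocol scale
(r₀ ≈ 10 μm, ΔC⁰/C_out ≈ 0.04) the two forms differ by under 1%; reported
theory values use the approximate form, which is the convention the
tabulated comparisons follow.

Under a DC field E the membrane potential is V_m = 1.5 R E (membrane
charging treated as instantaneous; Maxwell–Wagner dynamics are out of
scope) and the Maxwell stress loads the bilayer with

    σ_c = ε_m ε₀ (h / 2h_e²) V_m².

With ε_m = 4.5, h = 4 nm, h_e = 2.8 nm this is σ_c = c·(R E)² with
c = 22.87 mN/m per V² (CODATA ε₀; the conventional rounded coefficient is
22.86 — the last digit depends on the ε₀ precision used).

Pore nucleation is thermally activated escape over the prepore
free-energy barrier. A prepore of radius r in a membrane with pore-edge
line tension Γ and electrostatic term B costs

    U(r, σ_t) = 2πΓr − πr²(σ_t + B),

maximal at the critical radius r_c = Γ/(σ_t + B) with barrier
U_b = πΓ²/(σ_t + B). The mean-first-passage-time rate is

    k_p(σ_t) = A_F (σ_t + B) exp[−πΓ²/(kT(σ_t + B))],

strictly increasing in σ_t, which makes the inverse map well defined.
B is strictly an input constant (taken from electrostatic theory for the
given surface charge density); it is not derivable inside this package.

## Tension additivity and the curve-shift estimator

The central assumption is σ_t = σ_c + σ_os: electric and osmotic tension
load the membrane identically. Then the measured k_p at applied tension
σ_c under osmotic pressure equals the zero-pressure rate at σ_c + σ_os,
so inverting the zero-pressure rate law at the measured k_p and
subtracting σ_c estimates σ_os point by point. The estimator reports the
unweighted mean and the n−1 sample standard deviation over points; it is
exactly additive (feeding points generated at σ_c + s returns s with zero
spread, a property the tests assert to solver tolerance).

Inversion uses bracketed root finding (Brent) on the analytic log-rate,
with automatic upward bracket expansion from [10⁻⁶, 1] N/m; relative
tolerance is far below the 0.1 mN/m at which results are reported. The
equivalent-tension column of tabulated reference points reproduces to
±0.1 mN/m (their printed precision).

## Survival analysis

Each experiment observes n single vesicles for a fixed window (60 s by
default) from the instant the target field is reached (t = 0). The
empirical intact fraction is a step function dropping by the tied count
over n at each rupture-onset time; vesicles intact at the window end are
right-censored and stay in the denominator throughout.

Two rate estimators are provided:

- `survival-lsq` (default): unweighted nonlinear least squares of
  exp(−k t) against the step curve evaluated just after each drop and at
  the window end. This mirrors the conventional single-exponential decay
  fit; no weighting is applied since none is standard.
- `censored-mle`: the closed-form maximum-likelihood estimator for
  right-censored exponential data, n_ruptured / total exposure, with
  standard error k/√n_ruptured. Recommended for new data; used as a
  cross-check here.

Zero observed ruptures yield k_p = 0 flagged `lower-bound` rather than an
exception, since such data only bound the rate.

Rate-law fitting (`fit_kinetic_model`) is least squares in log k over
measured (σ_t, k_p) points, parameterised as (Γ in pN, log₁₀A_F) for
conditioning. B is fixed at its preset value by default — the reference
workflow quotes B separately from the fitted Γ and A_F — and a free-B
mode exists for four or more points.

## Solution bookkeeping

Osmolarities come from linear osmometer calibrations (sucrose:
1.029·C + 292.9; glucose: 1.010·C + 294.2, mOsm/L versus mM). The inside
osmolarity applies the pre-hydration dilution (default 20 μL water into
1 mL, i.e. ×1000/1020). The outside concentration is the volume-weighted
mix of chamber glucose and carried-over suspension sucrose (default
280 μL + 20 μL of 98 mM), and the glucose calibration is applied to the
*total* mixed solute concentration — a deliberate fidelity choice: it is
what reproduces the documented chain (76.6 mM chamber glucose → 78 mM
outside → 373 mOsm/L → ΔC⁰ = 15 mOsm/L). Exact values are kept
internally; integer mOsm/L and one-decimal mN/m appear only in reports.

Error propagation on the approximate tension uses quadrature of three
relative errors: ΔC⁰ (its absolute error taken as the linear sum of the
two osmometer readings, e.g. 5.6/13 = 0.43 — the dominant term), C_out
(one osmometer reading) and K_A. The ΔC⁰ error *reported alongside the
value* uses quadrature of the two readings (≈ ±4 mOsm/L); the two
conventions coexist deliberately and the discrepancy is logged. With
K_A = 141 mN/m and ΔC⁰ = 13 this yields σ_os = 3.3 ± 1.4 mN/m; published
tables of this kind sometimes print slightly smaller errors (±1.2),
consistent with a different unstated combination rule.

The surface charge density uses one elementary charge per DOPG headgroup
over the composition-weighted area per molecule,
Ω = −eX/[a_DOPG(1−C_h) + a_ch·C_h], giving −0.15 C/m² for the
cholesterol membrane. For the binary membrane the arithmetic gives
−0.088 C/m² (e·0.40/72.5 Ų); a commonly quoted rounded value is −0.10,
which does not follow from this arithmetic — the package reports the
computed value.

## Synthetic-data generator

The generator emulates the laboratory protocol, not the microscope: per
(tension, replicate) group it draws 18 vesicle radii (lognormal, median
10 μm, log-sd 0.2 — exemplar-based placeholders, since no dispersion
statistics are published) and one exponential rupture waiting time per
vesicle at rate k_p(σ_c + σ_os), right-censored at the 60 s window.
Defaults (18 vesicles per tension, 3 replicates, 60 s) are the protocol
scale. Tensions are specified directly by default (the experiment chooses
E per vesicle to hit a target σ_c); a field-driven mode can instead derive
σ_c from the sampled radius at fixed E.

Seeding is counter-based: each group's stream derives from the master
seed plus a CRC32 of its label, so adding an arm to a study never
perturbs existing arms and a fixed seed gives byte-identical output.

The ~7 s field ramp preceding the hold is excluded from the hazard by
default, matching the t = 0 convention of the analysis. `include_ramp`
adds the ramp exposure via Poisson thinning with σ_c(t) rising linearly
from the baseline-field tension (≈0.5 mN/m at 320 V/cm, 10 μm); it exists
to quantify the bias of the t = 0 convention and extends the record
window to ramp + hold.

What passing synthetic tests do **not** show about real data: the
generator assumes a perfectly constant tension per vesicle, exact
exponential waiting times, no radius–tension coupling by default, no
optical detection latency and no vesicle-to-vesicle compositional
variation. Recovery guarantees are therefore statements about the
estimator under the stated model, not about microscope data.

## Numerical and reporting conventions

- Strict SI internally; presentation converts to mN/m, pN, nm, mOsm/L.
  Tensions report to one decimal in mN/m, rates to two significant
  figures, osmolarities to integers.
- Defaults: T = 298.15 K (thermostat 25 ± 1 °C; a helper re-evaluates
  rates at T ± 1 K), a_ch = 35.5 Ų (midpoint of the 33–38 Ų range),
  leakage threshold σ_critical = 7 mN/m (the zero-pressure tension scale
  at which electric rupture sets in), all configurable.
- Survival fit initial guess is the censored MLE; curve-shift sd uses
  ddof = 1; ties in rupture times drop the step by the tied count.
- Problem sizes in the test suite: large-n checks use 10⁴ vesicles;
  protocol-scale calibration uses 18×3 with 200–500 seeded repetitions.
  At that scale the replicate-averaged rate estimate is within a factor
  of two of truth in ≥95% of runs and the end-to-end curve-shift
  estimate lands within ±0.5 mN/m of an injected 2.3 mN/m shift in ≥90%
  of runs; a single 18-vesicle replicate alone is noisier (≈94% for the
  least-squares fitter, ≈96% for the MLE).

## Known limitations

- The exponential-survival model ignores pore-closure dynamics and
  competing fates; vesicles that leak without full rupture are outside
  the generative model.
- B and K_A are inputs, never inferred.
- The hypertonic (shrinking) regime is flagged but not modelled.
- The full-form tension assumes linear elasticity and ΔC⁰ ≪ C_out;
  neither holds for large osmotic shocks.
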