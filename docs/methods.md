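# Methods

## Model

A virtual population of n subjects receives dose D (mg/kg) against a
pathogen of fixed MIC (mg/L). The free exposure index of subject i is

    fAUC/MIC_i = D / (CL_i * MIC)        (units: days)

with free clearance CL_i drawn from a lognormal law. The steady-state free
concentration under constant infusion is the same quotient with the dose
replaced by an infusion rate, so a single set of simulations covers both
read-outs; free exposure depends on free clearance only, never on binding
(encoded in `binding.css_infusion`, whose signature admits no binding
argument).

The observable total-concentration index divides each free value by that
subject's unbound fraction, fu_i, drawn independently of clearance:

    total(AUC/MIC)_i = fAUC/MIC_i / fu_i

Mechanistically fu = Kd/(Bmax + Kd) in the linear binding regime
(`binding` module); the pipeline itself only needs the operational division.
On the log scale the total index is a sum of independent terms, so
Var ln(total) = Var ln(reference) + Var ln(fu): the observable index is
strictly more variable whenever binding varies between subjects.

The analyst's back-computation multiplies the total distribution by an
assumed fu — a scalar, or a distribution whose draws are **independent** of
the generating draws, because in practice individual fu values are unknown.
(Pairing them would presuppose that knowledge and reconstruct the reference
exactly.) The back distribution keeps the reference median when the assumed
fu is centred correctly but inherits the inflated variance, so its lower
quantiles are biased low:

    Bias% = 100 * (Q10_back - Q10_ref) / Q10_ref

Dose correction uses strict dose linearity (every index value scales with
D): the grid rule steps the dose up by 0.5 mg/kg, rescales the *same* back
sample, and keeps the dose whose PTA at the target is closest to the goal
(ties to the lower, safety-conservative dose; search ceiling 10x the base
dose); the exact rule inverts the defining quantile,
D* = D * target / Q_{1-goal}(back).

## Default study conditions

| parameter | default | rationale |
| --- | --- | --- |
| dose | 10 mg/kg | base regimen from which corrections are expressed |
| MIC | 1 mg/L | without loss of generality (indices scale as 1/MIC) |
| clearance | lognormal, mean 7 L/kg/day, CV 10% | typical of minimally bound antimicrobials, whose total clearance variability (<20%) approximates the free one |
| moderate binding fu | lognormal, mean 0.5, CV 15% | vancomycin/ertapenem-like variability |
| high binding fu | uniform on [0.05, 0.15] | highly bound drugs, fu about 0.1, range-style literature reporting |
| assumed fu | scalar 0.5 / 0.1, or uniform [0.40, 0.60] / [0.05, 0.15] | the scalar and "add the variability" scaling practices |
| n | 5000 | desk-scale Monte Carlo; quantile SE well below the reported precision |
| seed | 12929 | arbitrary package default; every result is a pure function of it |

The (mean, CV) parameterization is canonical; log-scale (mu, sigma) are
derived via sigma^2 = ln(1 + CV^2), mu = ln(mean) - sigma^2/2, which
round-trips to machine precision. Lognormal fu draws are not truncated at
1: under mean 0.5, CV 15% the mass above 1 is about Phi(-4.7) and silent
truncation would change the distribution; the caveat is documented instead.

## Randomness

A scenario master seed spawns three named `SeedSequence` substreams
(clearance, generating fu, scaling fu) identified by fixed spawn keys, not
call order. Consequences: adding or dropping a stage never perturbs another
stage's draws; scenarios sharing a seed share their reference population
(and, for a common generating law, their total population), mirroring a
workflow in which one reference vector feeds every table row; and two runs
with equal configs are bitwise identical, which the report writer relies on
for byte-identical CSVs.

One fu draw per subject (elementwise vectors), never one draw per
replicate: the variance inflation that drives the bias exists only at the
individual level.

## Oracles and numerical choices

Every simulated distribution is, on the log scale, a sum of normal terms,
constants, and at most two +/- ln U terms with U uniform. With no uniform
terms the quantiles are closed-form (`exp(sum mu + z_q * sqrt(sum
sigma^2))`, documented tolerance 1e-10). Each uniform term is marginalized
by adaptive quadrature of the conditional lognormal CDF over its finite
support (nested quadrature when both generating and scaling fu are
uniform; absolute error below 1e-6), and quantiles are recovered by Brent
root-solving on the strictly increasing CDF, bracketed around the
closed-form guess with uniforms at their geometric midpoints. This was
chosen over 2-D density integration for robustness: the integrand is a
smooth, bounded CDF. Uniform clearance has no oracle and raises rather
than silently approximating.

Empirical quantiles use linear interpolation between order statistics
(numpy's default); at n = 5000 the difference between quantile conventions
is O(1/n), far below Monte Carlo noise. Target attainment uses the
inclusive `>=`; for continuous samples the boundary carries no mass, but
the convention is fixed so that attainment at a sample's own q-quantile is
1 - q up to interpolation. Degenerate (all-scalar) scenarios propagate
exactly: bias is identically zero and the exact dose equals the base dose.

## What the generator does and does not emulate

The scenario engine *is* the data generator: there is no external data. It
emulates between-subject variability of free clearance and of plasma-protein
binding as independent, stationary lognormal/uniform laws. It does not
emulate correlated clearance-binding physiology, saturable (concentration-
dependent) binding, covariate structure, multi-dose time courses, or assay
noise in measured concentrations. Passing tests therefore demonstrate the
internal consistency and calibration of the sampling-and-scaling pipeline
under these laws — the mechanism of the bias — not the magnitude of bias
for any particular drug, which depends on the real fu distribution.

Sizes used in the checks: headline statistics at n = 5000; oracle-agreement
checks at n = 10^6, where the asymptotic quantile standard error
sqrt(q(1-q)/n)/f(x_q) (density from a central difference of the oracle CDF)
gives a 3-SE acceptance band.

## Known limitations

- The bias of %fT>MIC-type indices is not modelled; it depends on dosing
  interval and shape parameters in ways a single-quotient index does not.
- No deconvolution: the package quantifies the bias of fu-scaling but does
  not recover the free distribution from an observed total one.
- Units are documented, not enforced; inputs in inconsistent units will be
  accepted silently.
- The oracle covers lognormal-or-scalar clearance with up to two uniform fu
  factors — exactly the scenario families the engine targets — not
  arbitrary user distributions.
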