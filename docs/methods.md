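# Methods

`cosas` refines an analytic scattering model simultaneously against several
small-angle scattering curves and benchmarks, by simulation, how the choice
of per-dataset weights and of priors affects the accuracy of the refined
parameters.  This note records the models, the synthetic-data generator,
the numerical choices, and what the benchmark does and does not show.

## Co-refinement objective

Given curves j = 1..J with points (q_i, I_i, sigma_i) and a model
I_model(q; x) with parameter vector x of length K, the fit minimizes

    Q(x) = sum_j w_j * chi2_j(x) + alpha * S(x),
    chi2_j = sum_i (I_ij - I_model(q_ij; x))^2 / sigma_ij^2,
    S      = sum_k ((x_k - mu_k) / s_k)^2,

where (mu_k, s_k) are the mean and width of the Gaussian prior of parameter
k and alpha weights the prior against the data.  Three weighting schemes
are implemented:

* naive: w_j = 1 — every point counts with its statistical error;
* reduced: w_j = 1/M_j — every dataset counts equally (reduced chi^2);
* information: w_j = N_g,BIFT,j / M_j — datasets count in proportion to
  their information content (number of good parameters, below).

Weights are realized by scaling the errors of dataset j with 1/sqrt(w_j)
and running one bounded least-squares solve on the stacked residual vector
(data residuals plus prior residuals sqrt(alpha)*(x_k - mu_k)/s_k), which
minimizes Q exactly.  The solver is `scipy.optimize.least_squares` (trust
region reflective) with an analytic Jacobian for the core–multishell model,
unit `x_scale`, and starting point mu.  Bounds are mu +- 5 s, floored at
zero for radii, lengths and scales; backgrounds are unconstrained in sign.
Non-converged solves are retried up to three times from starting points
perturbed by 1% of the prior widths, then flagged.

The hyperparameter alpha is chosen by scanning 11 log-spaced values
(default window 1e-2..1e2) and computing, at each, the Laplace-approximated
log evidence

    log p(alpha) = -Q(x_hat)/2 + (K_g/2) log alpha
                   - (1/2) log det(B + alpha * I) + const,

where B_kl = H_kl * s_k s_l / 2 is the prior-normalized Hessian of the
weighted data misfit (computed numerically by one-sided forward
differences, the convention the rest of the information-content machinery
also uses) and K_g counts the penalized parameters.  For a linear model
with Gaussian priors this expression is the exact marginal likelihood; the
test suite verifies that against the conjugate closed form.  The window
shifts by half a decade and rescans (up to eight times) until the evidence
maximum is interior.  Probabilities are normalized over the scan and the
reported parameters are the probability-weighted average of the per-alpha
fits.  Uniform-prior (bounded maximum-likelihood) fitting fixes
alpha = 1e-10, which quenches the penalty while keeping bounds and starting
values; all weighting-scheme benchmarks use this mode.

## Models

**Core–multishell sphere.** Amplitude of a homogeneous sphere
A(qR) = 3[sin(qR) - qR cos(qR)]/(qR)^3; the particle amplitude is the sum
of boundary-radius terms g_m V(R_m) A(qR_m) with coefficients g built from
the shell contrasts relative to the core.  Only contrast ratios shape the
curve, so the core contrast is fixed at 1 and each dataset carries three
relative shell contrasts, a scale a [1/cm] and a flat background b [1/cm]:
K = 9 for one dataset, K = 14 for two.  P(0) = 1 by construction and
I = a P + b.  An optional Percus–Yevick hard-sphere structure factor
(closed form, S(0) = (1-eta)^4/(1+2 eta)^2) multiplies P with fixed, not
refined, R_hs and eta; the benchmark uses R_hs = 70 A (the outermost
radius) and eta = 0.2, values chosen here as a typical concentrated-sample
condition since no published values exist for this cell.

**Stacked cylinders.** Three coaxial cylinders of common radius R and
lengths L_j stacked contiguously; the coherent amplitude sums
contrast * volume * [2 J1(x)/x] * sinc(q L_j cos b / 2) * exp(i q cos b d_j)
with center-to-center offsets d_1 = 0, d_j = L_1/2 + sum(L_2..L_{j-1}) +
L_j/2, and is orientation-averaged over b in [0, pi/2] with sin b weight by
128-node Gauss–Legendre quadrature (self-convergence < 1e-6 against 256
nodes).  The complex-exponential phase is kept because the stack is not
mirror-symmetric.  Contrasts are parameterized relative to the first
cylinder (two per dataset), giving K = 8 for one dataset and K = 12 for
two.  Equal contrasts reduce the stack to a single cylinder of the summed
length to 1e-8 relative, which the tests assert.

**Two-component mixture.** I = s (f_1 I_1 + (1-f_1) I_2) over tabulated
component curves, parameterized by the stoichiometric ratio r = f_2/f_1
(so f_1 = 1/(1+r)) and the overall scale s.  The ratio carries a
log-normal prior with median 1 — agnostic between the components — and
log-width 2, wide enough to be non-informative over four orders of
magnitude of r.

**Resolution smearing.** Where a curve carries per-point q widths sigma_q
(fourth data column), the model is averaged over a Gaussian kernel
truncated at +-3 sigma_q (truncation error < 1e-4 of the kernel mass),
renormalized over its support and over q > 0, with 5 nodes per sigma.  The
node density leaves <1% error at the sharp minima of a solid-sphere curve
(verified against a 4001-node convolution) and is exact for flat curves;
smearing is linear in the model.  Synthetic sigma_q columns are affine in
q (5e-4 + 0.05 q) with a multiplier hook for exaggerated-resolution
conditions (x2, x3).

## Synthetic data

Datasets are simulated on uniform q grids (benchmark: SAXS-like 300-2000
points, SANS-like 50-300 points, q = 0.001-0.5 1/A; SAXS a = 0.5 1/cm,
b = 1e-5 1/cm; SANS a = 0.8 1/cm, b = 1e-4 1/cm, the higher background
standing in for incoherent scattering).  Intensities are drawn
independently per point from Normal(I_model(q_i), sigma_i) — negative
samples are kept — with the empirical counting model

    sigma_i^2 = I_s(q_i) * (1 + 2c/(1-c)) / (k * q_i),
    I_s(q)    = s * I_model(q) / I(0),

mapped back to absolute units.  The bracket is the propagated Poisson
noise of buffer subtraction when the buffer contributes the fraction c of
the total sample intensity at every q (sample + buffer counts,
1 + 2c/(1-c) = (1+c)/(1-c)); 1/(k q) models the growth of the number of
detector pixels in a q bin.  SAXS-like data use s = 100, c = 0.85 and
SANS-like data s = 10, c = 0.95, giving SAXS the higher signal-to-noise
ratio.  The exposure constant k is not a published quantity; it was
calibrated once so that single-dataset refinement accuracy at the
equal-size (300:300) benchmark condition matches the published values, and
then frozen at k = 2000 A for all conditions, noise levels and tests.  At
these settings the relative error is ~0.8% (SAXS) and ~4% (SANS) at the
first grid point and grows toward high q as the signal decays.

A noise factor multiplies the variance before sampling (used to trace how
information content degrades with noise), and a separate mis-scaling
factor multiplies the *reported* errors after sampling (0.1 = highly
underestimated to 10 = highly overestimated), so the reported
uncertainties no longer describe the actual fluctuations.  Replicate r of
a condition is seeded with (base_seed + r, dataset_index), making every
benchmark cell reproducible in isolation.

What the generator does not emulate: count-based (Poisson) statistics,
instrument-specific resolution columns, inter-point correlations from data
reduction, polydispersity, or systematic errors other than the deliberate
error mis-scaling.  Passing benchmarks therefore demonstrate behaviour
under clean, independent-point Gaussian noise of realistic magnitude, not
under every artefact of real beamline data.

## Information content

**N_g from a model fit.** The chi^2 Hessian (forward differences,
relative step 1e-4; a central-difference cross-check is in the tests) is
normalized as B_kl = H_kl s_k s_l / 2 with the prior widths s_k (for
uniform priors, one fifth of the bound half-width serves as the width
surrogate), and N_g = sum lambda/(lambda + alpha) over its eigenvalues —
the count of parameter-space directions the data constrain more strongly
than the prior.  N_g -> K as alpha -> 0 and -> 0 as alpha -> infinity.

**Embedded BIFT.** The pair-distance distribution p(r) is fit as
I(q) = sum_j T_ij p_j + b with the sine-kernel matrix
T_ij = 4 pi dr sin(q_i r_j)/(q_i r_j) on (default) 100 interior r points
in (0, Dmax), non-negative p via NNLS on the augmented system, a
second-difference smoothness prior with implicit zeros at r = 0 and Dmax,
and a free flat background.  For each candidate Dmax the regularization
weight alpha maximizes the evidence

    log p(alpha) = -chi2/2 - alpha S/2 + (1/2) sum log(alpha/(alpha+lam)),

with lam the generalized eigenvalues of the curvature against the
smoothness operator; the alpha window adapts to the eigenvalue scale
(20 decades around the largest eigenvalue) and is refined by golden
section.  Dmax is scanned on a coarse grid and refined the same way.
N_g,BIFT = sum lam/(lam + alpha) at the optimum.  On low-noise solid-sphere
data the transform recovers Dmax within 5% of 2R, the analytic
r^2 (1 - 3r/4R + r^3/16R^3) distance distribution with cosine similarity
> 0.99, and reconstruction reduced chi^2 ~ 1; N_g,BIFT falls monotonically
as the noise factor grows.  If the evidence maximum sits on the search
boundary the boundary solution is returned flagged, and the Shannon count
(qmax - qmin) Dmax / pi is the documented fallback.  For the
information-weighting scheme inside replicated benchmarks, BIFT runs per
replicate with a reduced search (60 r points, 6 Dmax candidates, no
golden refinement) — N_g is insensitive to fine Dmax refinement, and only
the ratio N_g/M enters the weights.

**Degrees of freedom.** For a joint fit the total N_g is split across
datasets in proportion to their single-dataset upper limits n_g,j,
N_g,j = n_g,j N_g / n_all, so that sum_j N_g,j = N_g exactly;
DOF_j = M_j - N_g,j and reduced chi^2_j = chi2_j / DOF_j.  On correctly
simulated and correctly modelled fits the per-dataset reduced chi^2
centres on 1.0; the acceptance suite asserts 1.0 +- 0.2.

## Benchmark protocol

For each condition (model truth, dataset sizes, noise settings, prior
fixture, optional structure factor / extra core-contrast dataset /
resolution multiplier), n_rep replicates are simulated and refit.  The
accuracy of parameter k is the RMS deviation from truth with denominator
n_rep (the truth is known, so no degree of freedom is lost to a mean), and
a scheme's headline number is the mean of dx_k/|x_k,true| over the four
radii (nuisance parameters — contrasts, scales, backgrounds — are
excluded), in percent.  Percentile bootstrap over replicates gives 99%
confidence intervals.  The packaged prior fixtures are the benchmark's
truth-centred uniform sets (bounds truth +- m * s_best for m = 5..0.5) and
the three Gaussian sets (best/good/poor); the extra core-contrast dataset
uses contrasts 0 +- 0.01 in (-0.05, 0.05) and SANS-like scale/background
priors, mirroring the SANS contrast-prior pattern.

Replicate counts are 100-500 here versus the published 50000, so desk
results carry bootstrap uncertainties of roughly +-0.5-1.5 percentage
points where the original table quotes ~1%.  With the one-constant noise
model, the equal-size condition, the single-dataset references and the
scheme ordering (naive best, reduced worst, equal at equal sizes)
reproduce; the absolute deviations of the strongly unbalanced co-refined
conditions run up to ~1.5x the published values, which we attribute to the
reduction of the original per-q buffer curve to the single constant c.

## Known limitations

* One global exposure constant k cannot represent instruments whose
  buffer-to-sample ratio varies with q; the co-refined accuracy numbers
  inherit that approximation.
* The evidence uses the Laplace approximation; it is exact only for
  linear models, and the BIFT evidence ignores the non-negativity
  constraint's effect on the posterior volume.
* The stacked-cylinder model is implemented and tested for three
  cylinders; other counts run but are untested.
* No polydispersity, interface roughness, or MCMC posterior sampling.
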