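# cosas — co-refinement of small-angle scattering data

`cosas` fits an analytic scattering model *simultaneously* against several
SAXS/SANS curves, with configurable per-dataset weights and truncated
Gaussian priors, and ships the simulation benchmark that measures which
weighting scheme and which priors recover the true structural parameters
most accurately.

It is aimed at SAS practitioners and method developers who co-refine
contrast-variation data (synchrotron SAXS + SANS, multiple deuteration
contrasts) and need a defensible answer to two recurring questions: *how
should datasets of very different size and quality be weighted against
each other*, and *what do informative priors buy over plain parameter
bounds*?

## The model and the objective

The co-refinement minimizes

    Q = Σ_j w_j χ²_j + α S,        χ²_j = Σ_i (I_ij − I_model(q_ij; x))²/σ_ij²,
    S = Σ_k ((x_k − μ_k)/s_k)²,

over the shared parameter vector x, where j runs over datasets and
(μ_k, s_k) are Gaussian prior means and widths.  Weighting schemes:
**naive** w_j = 1, **reduced** w_j = 1/M_j (one vote per dataset), and
**information-based** w_j = N_g,BIFT,j/M_j, where N_g,BIFT is the number
of good parameters from an embedded Bayesian indirect Fourier transform —
the effective number of independent quantities the dataset determines.
The prior weight α is selected by scanning 11 log-spaced values and
maximizing the (Laplace) evidence; reported parameters are the
probability-weighted average over the scan.  Fixing α = 10⁻¹⁰ quenches
the prior and gives bounded maximum-likelihood fitting ("uniform priors").

Built-in models: a core–multishell sphere (4 radii + per-dataset relative
contrasts, scale, background; K = 9/14 for 1/2 datasets), three stacked
cylinders with phase factors, a Percus–Yevick hard-sphere structure
factor, a two-component mixture with a log-normal stoichiometry prior,
and Gaussian q-resolution smearing for 4-column (σ_q) data.

The benchmark simulates paired SANS-like (50–300 pts, noisy) and SAXS-like
(300–2000 pts, clean) datasets from a known truth with an empirical
counting-statistics error model, refits them thousands of times, and
scores each scheme by the average relative RMS deviation of the refined
radii from truth (Eq. details in `docs/methods.md`).  The headline result
it reproduces: **the naive scheme w_j = 1 is the most accurate**, the
reduced scheme is consistently the worst, and Gaussian priors sharpen
poorly determined parameters without hurting well-determined ones.

## Worked example

Simulate one SANS/SAXS pair from the benchmark truth (radii 10/30/50/70 Å)
and co-refine it with the naive scheme and uniform priors:

```python
import numpy as np
from cosas import (Condition, DatasetSpec, simulate_replicate,
                   fit_uniform, dataset_weights)

cond = Condition(name="demo",
                 datasets=[DatasetSpec(kind="sans", M=50),
                           DatasetSpec(kind="saxs", M=400)],
                 base_seed=11)
curves = simulate_replicate(cond, 0)          # one SANS + one SAXS curve
fit = fit_uniform(curves, cond.model(), cond.priors(), scheme="naive")
print(np.round(fit.x[:4], 2))                 # refined radii [Å]
print(np.round(fit.chi2_per_dataset / fit.M_per_dataset, 2))
```

Output:

```
[ 7.45 31.49 51.5  70.39]
[0.64 1.06]
```

The outer radii come back within ~1.5 Å of the truth while the 10 Å core
— the particle's softest parameter, carrying the least scattering weight —
lands 2.5 Å off in this single noisy replicate; that spread is exactly
what the replicated benchmark quantifies.  The per-dataset χ²/M near 1
says the fit is statistically consistent with the simulated errors.  The same workflow is scriptable from the shell:

```bash
cosas simulate --preset saxs400 --seed 1 -o saxs.dat
cosas simulate --preset sans50  --seed 2 -o sans.dat
cosas fit --config demo.yaml --scheme naive --uniform-priors
cosas bift saxs.dat --dmax-min 60 --dmax-max 250 --output pr.dat
cosas evaluate --grid table1 --conditions coreshell_300_300 \
               --schemes naive,reduced --nrep 50 --out grid.csv
```

where `demo.yaml` lists the dataset paths/kinds, the model name, the prior
fixture and the weighting scheme.

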