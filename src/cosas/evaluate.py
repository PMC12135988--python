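"""Replicated simulate-and-fit experiments and parameter-recovery metrics.

A *condition* bundles the true model, the per-dataset simulation settings
and the prior fixture.  For each replicate, fresh datasets are simulated
and the model is refined with one or more weighting schemes (and optionally
against each dataset alone); the accuracy of a scheme is summarized by the
RMS deviation of each refined structural parameter from its true value,

    dx_k = sqrt( (1/n_rep) sum_r (x_k,r - x_k,true)^2 ),

and by the average relative deviation over the structural parameters,
mean_k dx_k / |x_k,true|, in percent.  The denominator is n_rep (not
n_rep - 1) because the true value is known, leaving zero degrees of
freedom.  Bootstrap resampling over replicates gives confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import io as cio
from .corefine import dataset_weights, fit_gaussian, fit_uniform
from .infocontent import bift
from .models import CoreMultiShellModel, get_model
from .simulate import (SANS_NOISE, SAXS_NOISE, NoiseSpec, misscale_errors,
                       simulate_dataset, synth_sigma_q)

__all__ = [
    "DatasetSpec",
    "Condition",
    "EvalResult",
    "rms_deviation",
    "avg_rel_deviation",
    "bootstrap_ci",
    "simulate_replicate",
    "run_condition",
    "evaluate_replicates",
    "error_misscale_sweep",
    "prior_quality_sweep",
    "table1_conditions",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rms_deviation(values, x_true) -> float:
    """RMS deviation from the known truth, denominator n_rep."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values supplied")
    return float(np.sqrt(np.mean((values - x_true) ** 2)))


def avg_rel_deviation(deltas, x_true) -> float:
    """Mean of dx_k/|x_true,k| over the structural parameters, in percent."""
    deltas = np.asarray(deltas, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if deltas.shape != x_true.shape:
        raise ValueError("parameter sets do not match")
    if np.any(x_true == 0):
        raise ValueError("relative deviation undefined for zero truth value")
    return float(np.mean(deltas / np.abs(x_true)) * 100.0)


def bootstrap_ci(per_replicate, x_true, level=0.99, n_boot=500, seed=0):
    """Percentile bootstrap interval for the average relative deviation.

    ``per_replicate`` has shape (n_rep, n_struct); replicates are resampled
    with replacement and the full metric recomputed for each resample.
    """
    vals = np.asarray(per_replicate, dtype=float)
    n_rep = vals.shape[0]
    if n_rep < 10:
        raise ValueError("need at least 10 replicates for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_rep, n_rep)
        deltas = np.sqrt(np.mean((vals[idx] - x_true) ** 2, axis=0))
        stats[b] = avg_rel_deviation(deltas, x_true)
    tail = (1.0 - level) / 2.0
    return (float(np.quantile(stats, tail)),
            float(np.quantile(stats, 1.0 - tail)))


@dataclass
class EvalResult:
    """Accuracy summary for one condition/scheme."""

    param_names: list
    x_true: np.ndarray
    deltas: np.ndarray             # per-parameter RMS deviation
    rel_deviations: np.ndarray     # deltas / |truth|
    avg_rel_dev: float             # percent
    ci: Optional[tuple] = None     # bootstrap CI on avg_rel_dev
    per_replicate: Optional[np.ndarray] = None
    n_failures: int = 0
    flagged: bool = False


def evaluate_replicates(per_replicate, x_true, param_names=None,
                        ci_level=0.99, n_boot=500, with_ci=True) -> EvalResult:
    vals = np.asarray(per_replicate, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    deltas = np.sqrt(np.mean((vals - x_true) ** 2, axis=0))
    rel = deltas / np.abs(x_true)
    ci = bootstrap_ci(vals, x_true, level=ci_level, n_boot=n_boot) \
        if with_ci and vals.shape[0] >= 10 else None
    return EvalResult(param_names=list(param_names or []), x_true=x_true,
                      deltas=deltas, rel_deviations=rel,
                      avg_rel_dev=avg_rel_deviation(deltas, x_true), ci=ci,
                      per_replicate=vals)


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """Simulation settings for one dataset of a condition."""

    kind: str                    # 'saxs', 'sans' or 'core'
    M: int
    qmin: float = 0.001
    qmax: float = 0.5
    noise: Optional[NoiseSpec] = None
    sigma_q_multiplier: Optional[float] = None
    misscale: float = 1.0

    def __post_init__(self):
        if self.noise is None:
            self.noise = SAXS_NOISE if self.kind == "saxs" else SANS_NOISE


@dataclass
class Condition:
    """One benchmark cell: truth, datasets, priors, replication settings."""

    name: str
    datasets: Sequence[DatasetSpec]
    radii_true: Sequence[float] = cio.RADII_TRUE
    prior_fixture: str = "Uniform_5sigma"
    n_rep: int = 500
    base_seed: int = 1
    hardsphere: Optional[tuple] = None   # (R_hs, eta), fixed in sim and fit

    def truth_vector(self, dataset_indices=None):
        """Full true parameter vector for the joint (or single-dataset) model."""
        idx = range(len(self.datasets)) if dataset_indices is None \
            else dataset_indices
        x = list(self.radii_true)
        for j in idx:
            contrasts, a, b = cio.DATASET_TRUTH[self.datasets[j].kind]
            x.extend(contrasts)
            x.extend([a, b])
        return np.array(x, dtype=float)

    def model(self, dataset_indices=None):
        n = len(self.datasets) if dataset_indices is None \
            else len(dataset_indices)
        return CoreMultiShellModel(n_datasets=n, hardsphere=self.hardsphere)

    def priors(self, dataset_indices=None):
        idx = range(len(self.datasets)) if dataset_indices is None \
            else dataset_indices
        kinds = [self.datasets[j].kind for j in idx]
        return cio.build_prior_set(self.prior_fixture, kinds)


def simulate_replicate(cond: Condition, r: int):
    """Simulate all datasets of replicate ``r`` (deterministic in base_seed)."""
    model = cond.model()
    x_true = cond.truth_vector()
    curves = []
    for j, spec in enumerate(cond.datasets):
        sigma_q = None
        if spec.sigma_q_multiplier is not None:
            q_probe = np.linspace(spec.qmin, spec.qmax, spec.M)
            sigma_q = synth_sigma_q(q_probe,
                                    multiplier=spec.sigma_q_multiplier)
        curve = simulate_dataset(
            lambda q, j=j: model.eval_dataset(j, q, x_true),
            spec.qmin, spec.qmax, spec.M, spec.noise, sigma_q=sigma_q,
            seed=(cond.base_seed + r, j), label=f"{spec.kind}{j}")
        if spec.misscale != 1.0:
            curve = misscale_errors(curve, spec.misscale)
        curves.append(curve)
    return curves


_SCHEMES = ("naive", "reduced", "information")


def run_condition(cond: Condition, schemes=("naive",), singles=(),
                  gaussian=False, n_rep=None, bift_kwargs=None,
                  collect_all_params=False):
    """Run the replicated simulate-and-fit experiment for one condition.

    Returns ``(results, n_failures)`` where results maps each requested key
    (scheme name, or 'single:<kind>') to an array of refined structural
    parameters with shape (n_rep, n_struct).  Replicate-level fit failures
    are counted and the run is flagged (warning) above 5%.
    """
    n_rep = n_rep or cond.n_rep
    bift_kwargs = dict(n_r=60, n_dmax=6, refine_dmax=False) \
        if bift_kwargs is None else bift_kwargs
    joint_model = cond.model()
    struct = joint_model.structural_indices
    priors = cond.priors()
    keys = list(schemes) + [f"single:{k}" for k in singles]
    results = {k: np.empty((n_rep, len(struct))) for k in keys}
    failures = 0

    single_setup = {}
    for kind in singles:
        j = next(i for i, s in enumerate(cond.datasets) if s.kind == kind)
        single_setup[kind] = (j, cond.model([j]), cond.priors([j]),
                              cond.truth_vector([j]))

    for r in range(n_rep):
        curves = simulate_replicate(cond, r)
        ng = None
        for scheme in schemes:
            if scheme == "information" and ng is None:
                ng = [bift(c, **bift_kwargs).ng for c in curves]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = (fit_gaussian if gaussian else fit_uniform)(
                    curves, joint_model, priors, scheme=scheme, ng_bift=ng)
            if not fit.success:
                failures += 1
            results[scheme][r] = fit.x[struct]
        for kind in singles:
            j, s_model, s_priors, _ = single_setup[kind]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = (fit_gaussian if gaussian else fit_uniform)(
                    [curves[j]], s_model, s_priors, scheme="naive")
            if not fit.success:
                failures += 1
            results[f"single:{kind}"][r] = fit.x[s_model.structural_indices]

    if failures > 0.05 * n_rep * len(keys):
        warnings.warn(f"{cond.name}: {failures} fit failures "
                      f"(>5% of replicate fits); results flagged")
    return results, failures


def error_misscale_sweep(cond: Condition, factors, dataset_index,
                         scheme="naive", n_rep=None):
    """Re-run a condition with the reported errors of one dataset mis-scaled.

    Returns a dict factor -> EvalResult for the structural parameters.
    """
    out = {}
    for m in factors:
        if m <= 0:
            raise ValueError("mis-scaling factors must be positive")
        datasets = [replace(s) for s in cond.datasets]
        datasets[dataset_index] = replace(datasets[dataset_index], misscale=m)
        sub = replace(cond, datasets=datasets,
                      name=f"{cond.name}_misscale_{m:g}")
        res, _ = run_condition(sub, schemes=(scheme,), n_rep=n_rep)
        out[m] = evaluate_replicates(res[scheme], np.asarray(cond.radii_true),
                                     param_names=["R_c", "R_1", "R_2", "R_3"],
                                     with_ci=False)
    return out


def prior_quality_sweep(cond: Condition, fixtures, scheme="naive",
                        n_rep=None):
    """Run Gaussian/uniform prior fixtures on one condition (alpha-scan fits
    for the Gaussian fixtures, quenched fits for the uniform ones)."""
    out = {}
    for fx in fixtures:
        sub = replace(cond, prior_fixture=fx, name=f"{cond.name}_{fx}")
        res, _ = run_condition(sub, schemes=(scheme,),
                               gaussian=fx.startswith("Gaussian"),
                               n_rep=n_rep)
        out[fx] = evaluate_replicates(res[scheme], np.asarray(cond.radii_true),
                                      param_names=["R_c", "R_1", "R_2", "R_3"],
                                      with_ci=False)
    return out


# ---------------------------------------------------------------------------
# condition registry (the benchmark grid)
# ---------------------------------------------------------------------------

def table1_conditions(n_rep=500, base_seed=1) -> dict:
    """The core-multishell benchmark grid: paired SANS/SAXS simulations at
    several size ratios, an extra core-contrast dataset, a hard-sphere
    structure factor, and exaggerated SANS resolution."""

    def pair(m_sans, m_saxs, **kw):
        return [DatasetSpec(kind="sans", M=m_sans, **kw),
                DatasetSpec(kind="saxs", M=m_saxs)]

    conds = {
        "coreshell_300_300": Condition(
            name="coreshell_300_300", datasets=pair(300, 300)),
        "coreshell_50_400": Condition(
            name="coreshell_50_400", datasets=pair(50, 400)),
        "coreshell_50_900": Condition(
            name="coreshell_50_900", datasets=pair(50, 900)),
        "coreshell_50_2000": Condition(
            name="coreshell_50_2000", datasets=pair(50, 2000)),
        "core_contrast_50_400": Condition(
            name="core_contrast_50_400",
            datasets=pair(50, 400) + [DatasetSpec(kind="core", M=50)]),
        "core_contrast_50_2000": Condition(
            name="core_contrast_50_2000",
            datasets=pair(50, 2000) + [DatasetSpec(kind="core", M=50)]),
        "hardsphere_50_400": Condition(
            name="hardsphere_50_400", datasets=pair(50, 400),
            hardsphere=(70.0, 0.2)),
        "hardsphere_50_2000": Condition(
            name="hardsphere_50_2000", datasets=pair(50, 2000),
            hardsphere=(70.0, 0.2)),
    }
    for mult in (1.0, 2.0, 3.0):
        for m_saxs in (400, 2000):
            name = f"sans_res_x{mult:g}_50_{m_saxs}"
            conds[name] = Condition(
                name=name,
                datasets=[DatasetSpec(kind="sans", M=50,
                                      sigma_q_multiplier=mult),
                          DatasetSpec(kind="saxs", M=m_saxs)])
    for c in conds.values():
        c.n_rep = n_rep
        c.base_seed = base_seed
    return conds
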