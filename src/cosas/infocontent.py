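"""Information content of scattering data: Hessians, numbers of good
parameters, an embedded Bayesian indirect Fourier transform (BIFT), Shannon
channels, and degrees-of-freedom bookkeeping for reduced chi^2.

The number of good parameters N_g counts, through the eigenvalue weighting
lambda/(lambda + alpha) of a prior-normalized curvature matrix, how many
independent directions in parameter space the data actually determine.  For
a raw dataset this is obtained from the BIFT posterior (N_g,BIFT); for a
model fit it is obtained from the numeric Hessian of chi^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import nnls

from .simulate import Curve

__all__ = [
    "numeric_hessian",
    "ng_from_hessian",
    "PrDistribution",
    "bift",
    "shannon_channels",
    "DofTable",
    "dof_partition",
]


# ---------------------------------------------------------------------------
# Hessian-based N_g for model fits
# ---------------------------------------------------------------------------

def numeric_hessian(objective, params, rel_step=1e-4):
    """Forward-difference Hessian of a scalar objective, symmetrized.

    Step for parameter k is ``rel_step * max(|x_k|, 1)``.  One-sided
    (forward) differences are used throughout.
    """
    x0 = np.asarray(params, dtype=float)
    K = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective not finite at the expansion point")
    # single-step values f(x + h_k e_k)
    f1 = np.empty(K)
    for k in range(K):
        xk = x0.copy()
        xk[k] += h[k]
        f1[k] = objective(xk)
        if not np.isfinite(f1[k]):
            raise ValueError(f"objective not finite when stepping parameter {k}")
    H = np.empty((K, K))
    for k in range(K):
        for l in range(k, K):
            xkl = x0.copy()
            xkl[k] += h[k]
            xkl[l] += h[l]
            fkl = objective(xkl)
            if not np.isfinite(fkl):
                raise ValueError(
                    f"objective not finite when stepping parameters {k},{l}")
            H[k, l] = H[l, k] = (fkl - f1[k] - f1[l] + f0) / (h[k] * h[l])
    return 0.5 * (H + H.T)


def ng_from_hessian(hessian, scales, alpha, eig_tol=1e-8):
    """Number of good parameters from a chi^2 Hessian.

    The Hessian is normalized by the prior widths, B_kl = H_kl s_k s_l / 2,
    and N_g = sum_i lambda_i / (lambda_i + alpha) over its eigenvalues.
    """
    H = np.asarray(hessian, dtype=float)
    s = np.asarray(scales, dtype=float)
    B = H * np.outer(s, s) / 2.0
    lam = np.linalg.eigvalsh(0.5 * (B + B.T))
    if np.any(lam < -eig_tol * max(1.0, np.abs(lam).max())):
        warnings.warn("negative Hessian eigenvalues: expansion point may be "
                      "a saddle; clipping to zero")
    lam = np.maximum(lam, 0.0)
    return float(np.sum(lam / (lam + alpha)))


# ---------------------------------------------------------------------------
# BIFT
# ---------------------------------------------------------------------------

@dataclass
class PrDistribution:
    """Pair-distance distribution from an indirect Fourier transform."""

    r: np.ndarray
    pr: np.ndarray
    dmax: float
    alpha: float
    ng: float
    chi2: float
    chi2_reduced: float
    log_evidence: float
    background: float = 0.0
    converged: bool = True


def _bift_design(q, dmax, n_r):
    """Sine-kernel transform matrix on an interior r grid (p=0 at 0, Dmax)."""
    dr = dmax / (n_r + 1)
    r = dr * np.arange(1, n_r + 1)
    qr = np.outer(q, r)
    T = 4.0 * np.pi * dr * np.sin(qr) / qr
    return r, T


def _second_diff(n_r):
    """Second-difference operator with implicit zero boundaries."""
    D = np.zeros((n_r, n_r))
    for i in range(n_r):
        D[i, i] = -2.0
        if i > 0:
            D[i, i - 1] = 1.0
        if i < n_r - 1:
            D[i, i + 1] = 1.0
    return D


def _bift_solve(A, y, D, alpha, n_r):
    """Non-negative p minimizing ||A p - y||^2 + alpha ||D p||^2.

    The trailing two columns of A are a +-background pair and are excluded
    from the smoothness penalty.
    """
    rows = np.vstack([A, np.sqrt(alpha) * np.hstack(
        [D, np.zeros((n_r, A.shape[1] - n_r))])])
    rhs = np.concatenate([y, np.zeros(n_r)])
    coef, _ = nnls(rows, rhs)
    return coef


def _bift_evidence_at(q, I, sigma, dmax, alpha, n_r, eig=None):
    r, T = _bift_design(q, dmax, n_r)
    # free constant background through a +/- column pair (keeps nnls valid)
    ones = np.ones((len(q), 1))
    A = np.hstack([T, ones, -ones]) / sigma[:, None]
    y = I / sigma
    D = _second_diff(n_r)
    coef = _bift_solve(A, y, D, alpha, n_r)
    p = coef[:n_r]
    bkg = coef[n_r] - coef[n_r + 1]
    resid = A @ coef - y
    chi2 = float(resid @ resid)
    S = float(p @ (D.T @ D) @ p)
    if eig is None:
        B = (T / sigma[:, None]).T @ (T / sigma[:, None])
        L = D.T @ D
        eig = np.maximum(eigh(B, L, eigvals_only=True), 0.0)
    ng = float(np.sum(eig / (eig + alpha)))
    log_ev = (-0.5 * chi2 - 0.5 * alpha * S
              + 0.5 * np.sum(np.log(alpha / (alpha + eig))))
    return {"r": r, "p": p, "bkg": bkg, "chi2": chi2, "S": S, "ng": ng,
            "log_ev": log_ev, "eig": eig}


def _best_alpha(q, I, sigma, dmax, n_r, alpha_grid=None):
    """Coarse alpha scan followed by golden-section refinement.

    The default scan window adapts to the eigenvalue spectrum of the
    prior-normalized curvature: the crossover between data-dominated and
    smoothness-dominated regimes happens at alpha ~ lambda, so the grid
    spans many decades around the largest eigenvalue.
    """
    r, T = _bift_design(q, dmax, n_r)
    B = (T / sigma[:, None]).T @ (T / sigma[:, None])
    L = _second_diff(n_r).T @ _second_diff(n_r)
    eig = np.maximum(eigh(B, L, eigvals_only=True), 0.0)
    if alpha_grid is None:
        top = np.log10(max(eig.max(), 1e-30))
        alpha_grid = np.logspace(top - 16, top + 4, 21)
    best = None
    evs = []
    for a in alpha_grid:
        out = _bift_evidence_at(q, I, sigma, dmax, a, n_r, eig=eig)
        evs.append(out["log_ev"])
        if best is None or out["log_ev"] > best[1]["log_ev"]:
            best = (a, out)
    evs = np.array(evs)
    i = int(np.argmax(evs))
    boundary = i == 0 or i == len(alpha_grid) - 1
    # golden-section refine in log-alpha around the coarse maximum
    la = np.log(alpha_grid[max(i - 1, 0)])
    lb = np.log(alpha_grid[min(i + 1, len(alpha_grid) - 1)])
    gr = 0.5 * (np.sqrt(5.0) - 1.0)
    c = lb - gr * (lb - la)
    d = la + gr * (lb - la)
    fc = _bift_evidence_at(q, I, sigma, dmax, np.exp(c), n_r, eig=eig)
    fd = _bift_evidence_at(q, I, sigma, dmax, np.exp(d), n_r, eig=eig)
    for _ in range(12):
        if fc["log_ev"] > fd["log_ev"]:
            lb, d, fd = d, c, fc
            c = lb - gr * (lb - la)
            fc = _bift_evidence_at(q, I, sigma, dmax, np.exp(c), n_r, eig=eig)
        else:
            la, c, fc = c, d, fd
            d = la + gr * (lb - la)
            fd = _bift_evidence_at(q, I, sigma, dmax, np.exp(d), n_r, eig=eig)
    out = fc if fc["log_ev"] > fd["log_ev"] else fd
    alpha = np.exp(c) if fc["log_ev"] > fd["log_ev"] else np.exp(d)
    if best[1]["log_ev"] > out["log_ev"]:
        alpha, out = best
    return alpha, out, boundary


def bift(curve: Curve, n_r=100, dmax_range=(20.0, 400.0), n_dmax=8,
         alpha_grid=None, refine_dmax=True) -> PrDistribution:
    """Bayesian indirect Fourier transform of one curve.

    Fits I(q) = sum_j T_ij p_j + b with a second-derivative smoothness prior
    and non-negative p(r), selecting the regularization weight alpha and the
    maximum particle dimension Dmax by maximizing the evidence.  Returns the
    evidence-optimal p(r) together with N_g,BIFT, the eigenvalue-weighted
    count of independent parameters supported by the data.
    """
    q, I, sigma = curve.q, curve.I, curve.sigma
    dmax_candidates = np.linspace(dmax_range[0], dmax_range[1], n_dmax)
    results = {}

    def eval_dmax(dm):
        if dm not in results:
            results[dm] = _best_alpha(q, I, sigma, dm, n_r, alpha_grid)
        return results[dm][1]["log_ev"]

    evs = np.array([eval_dmax(dm) for dm in dmax_candidates])
    i = int(np.argmax(evs))
    boundary_dmax = i in (0, len(dmax_candidates) - 1)
    dm_best = dmax_candidates[i]
    if refine_dmax and not boundary_dmax:
        la = dmax_candidates[i - 1]
        lb = dmax_candidates[i + 1]
        gr = 0.5 * (np.sqrt(5.0) - 1.0)
        c = lb - gr * (lb - la)
        d = la + gr * (lb - la)
        for _ in range(10):
            if eval_dmax(c) > eval_dmax(d):
                lb, d = d, c
                c = lb - gr * (lb - la)
            else:
                la, c = c, d
                d = la + gr * (lb - la)
        dm_best = c if eval_dmax(c) > eval_dmax(d) else d

    alpha, out, boundary_alpha = results[dm_best]
    if boundary_dmax or boundary_alpha:
        warnings.warn("BIFT evidence maximum at the edge of the search range; "
                      "returning the boundary solution (consider Shannon "
                      "channels as a fallback)")
    ng = out["ng"]
    dof = max(curve.M - ng, 1.0)
    return PrDistribution(r=out["r"], pr=out["p"], dmax=float(dm_best),
                          alpha=float(alpha), ng=float(ng),
                          chi2=out["chi2"], chi2_reduced=out["chi2"] / dof,
                          log_evidence=float(out["log_ev"]),
                          background=float(out["bkg"]),
                          converged=not (boundary_dmax or boundary_alpha))


def shannon_channels(qmin, qmax, dmax) -> float:
    """Sampling-theorem count of independent channels,
    N_s = (qmax - qmin) * Dmax / pi."""
    if qmin < 0 or qmax <= qmin or dmax <= 0:
        raise ValueError("require 0 <= qmin < qmax and dmax > 0")
    return (qmax - qmin) * dmax / np.pi


# ---------------------------------------------------------------------------
# DOF partitioning
# ---------------------------------------------------------------------------

class DegenerateDatasetError(ValueError):
    pass


@dataclass
class DofTable:
    """Per-dataset split of the total number of good parameters.

    N_g,j = n_g,j * N_g / n_all distributes the joint-fit N_g across
    datasets in proportion to their single-dataset upper limits n_g,j, so
    that sum_j N_g,j = N_g exactly; DOF_j = M_j - N_g,j.
    """

    ng_upper: np.ndarray       # n_g,j
    ng_partitioned: np.ndarray  # N_g,j
    M: np.ndarray
    dof: np.ndarray
    chi2: np.ndarray
    chi2_reduced: np.ndarray
    ng_total: float

    @property
    def dof_total(self):
        return float(self.M.sum() - self.ng_total)


def dof_partition(ng_upper, ng_total, M, chi2_values) -> DofTable:
    ng_upper = np.asarray(ng_upper, dtype=float)
    M = np.asarray(M, dtype=float)
    chi2_values = np.asarray(chi2_values, dtype=float)
    if np.any(ng_upper <= 0):
        raise ValueError("upper-limit good-parameter counts must be positive")
    n_all = ng_upper.sum()
    if ng_total > n_all + 1e-9:
        raise ValueError("total N_g exceeds the sum of per-dataset limits")
    ng_j = ng_upper * ng_total / n_all
    if np.any(ng_j >= M):
        raise DegenerateDatasetError(
            "a dataset has fewer points than its share of good parameters")
    dof = M - ng_j
    return DofTable(ng_upper=ng_upper, ng_partitioned=ng_j, M=M, dof=dof,
                    chi2=chi2_values, chi2_reduced=chi2_values / dof,
                    ng_total=float(ng_total))
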