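"""Analytic small-angle scattering models.

Form factors for a spherical core–multishell particle and for stacked
cylinders, a Percus–Yevick hard-sphere structure factor, a two-component
mixture model, and Gaussian q-resolution smearing.

Conventions
-----------
* q in 1/Angstrom, lengths in Angstrom, absolute intensities in 1/cm.
* Form factors are normalized so that P(0) = 1; the measured intensity is
  I(q) = a * P(q) + b  (optionally times a structure factor S(q)).
* Scattering contrasts enter only through their ratios, so each model fixes
  one contrast (the core, or the first cylinder) to unity and refines the
  others relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j1

__all__ = [
    "ShellSphereParams",
    "StackedCylinderParams",
    "MixtureParams",
    "sphere_amplitude",
    "coreshell_intensity",
    "cylinder_amplitude",
    "stacked_cylinder_intensity",
    "hardsphere_structure_factor",
    "mixture_intensity",
    "smear_model",
    "ScatteringModel",
    "CoreMultiShellModel",
    "StackedCylinderModel",
    "MixtureModel",
    "MODEL_REGISTRY",
    "get_model",
]

# Below this argument the sinc-like terms switch to their series expansion;
# at 1e-2 both branches agree to ~1e-11 relative (the direct sphere form
# loses ~3 eps/x^2 to cancellation, the series truncates at O(x^6)).
_SMALL = 1e-2


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their physical constraints."""


class GridMismatchError(ValueError):
    """Raised when tabulated curves do not share a common q grid."""


# ---------------------------------------------------------------------------
# elementary amplitudes
# ---------------------------------------------------------------------------

def sphere_amplitude(q, R):
    """Form-factor amplitude of a homogeneous sphere, A(0) = 1.

    A(q) = 3 [sin(qR) - qR cos(qR)] / (qR)^3
    """
    if R <= 0:
        raise InvalidParameterError(f"sphere radius must be positive, got {R}")
    q = np.asarray(q, dtype=float)
    x = q * R
    small = np.abs(x) < _SMALL
    xs = np.where(small, 1.0, x)
    out = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    # series: 1 - x^2/10 + x^4/280
    out = np.where(small, 1.0 - x**2 / 10.0 + x**4 / 280.0, out)
    return out if out.ndim else float(out)


def _sinc(x):
    """sin(x)/x with the limit 1 at x = 0 (numpy.sinc uses pi-scaling)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def _bessel_term(x):
    """2 J1(x)/x with its small-argument limit 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SMALL
    xs = np.where(small, 1.0, x)
    out = 2.0 * j1(xs) / xs
    return np.where(small, 1.0 - x**2 / 8.0, out)


def cylinder_amplitude(q, R, L, beta):
    """Form-factor amplitude of a cylinder at orientation angle beta.

    Product of the radial term 2 J1(qR sin b)/(qR sin b) and the axial term
    sin(qL cos b / 2)/(qL cos b / 2); both tend to 1 as their argument -> 0.
    """
    if R <= 0 or L <= 0:
        raise InvalidParameterError("cylinder dimensions must be positive")
    q = np.asarray(q, dtype=float)
    beta = np.asarray(beta, dtype=float)
    radial = _bessel_term(q * R * np.sin(beta))
    axial = _sinc(q * L * np.cos(beta) / 2.0)
    return radial * axial


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _sphere_volume(R):
    return 4.0 * np.pi * R**3 / 3.0


@dataclass
class ShellSphereParams:
    """Core–multishell sphere: core radius, shell outer radii, contrasts.

    ``rel_contrasts`` are the shell contrasts relative to the core,
    Delta-rho_j / Delta-rho_c, one per shell.
    """

    R_c: float
    shell_radii: Sequence[float]  # outer radii R_1 < R_2 < ... strictly increasing
    rel_contrasts: Sequence[float]
    scale: float = 1.0
    background: float = 0.0
    # validate=False skips the ordering/positivity checks so that bounded
    # optimizers may evaluate transiently unphysical parameter vectors
    validate: bool = True

    def __post_init__(self):
        if len(self.rel_contrasts) != len(self.shell_radii):
            raise InvalidParameterError("one relative contrast per shell required")
        if not self.validate:
            return
        radii = [self.R_c, *self.shell_radii]
        if any(r <= 0 for r in radii):
            raise InvalidParameterError("all radii must be positive")
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise InvalidParameterError(
                f"radii must be strictly increasing, got {radii}"
            )
        if self.scale <= 0:
            raise InvalidParameterError("scale must be positive")


@dataclass
class StackedCylinderParams:
    """Cylinders of common radius stacked contiguously along their axis.

    ``rel_contrasts`` are contrasts of cylinders 2..n relative to cylinder 1.
    """

    R: float
    lengths: Sequence[float]
    rel_contrasts: Sequence[float]  # length n_c - 1
    scale: float = 1.0
    background: float = 0.0
    validate: bool = True

    def __post_init__(self):
        if len(self.lengths) < 1:
            raise InvalidParameterError("need at least one cylinder")
        if len(self.rel_contrasts) != len(self.lengths) - 1:
            raise InvalidParameterError(
                "need one relative contrast per cylinder beyond the first"
            )
        if not self.validate:
            return
        if self.R <= 0 or any(L <= 0 for L in self.lengths):
            raise InvalidParameterError("cylinder dimensions must be positive")
        if self.scale <= 0:
            raise InvalidParameterError("scale must be positive")


@dataclass
class MixtureParams:
    """Linear two-component mixture with overall scale."""

    f_sym: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.f_sym <= 1.0:
            raise InvalidParameterError("f_sym must lie in [0, 1]")
        if self.scale <= 0:
            raise InvalidParameterError("scale must be positive")

    @property
    def f_asym(self):
        return 1.0 - self.f_sym


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def coreshell_intensity(q_grid, params: ShellSphereParams):
    """Intensity a*P(q)+b of a core–multishell sphere, P(0) = 1.

    The amplitude is the contrast-weighted sum of successive-shell
    differences of volume-weighted sphere amplitudes; the core contrast is
    fixed to 1 (only contrast ratios affect the curve shape).
    """
    q = np.asarray(q_grid, dtype=float)
    radii = np.array([params.R_c, *params.shell_radii], dtype=float)
    contrasts = np.array([1.0, *params.rel_contrasts], dtype=float)
    # volume-weighted amplitudes for every boundary radius (R = 0 -> 0)
    VA = np.stack([
        _sphere_volume(R) * sphere_amplitude(q, R) if R > 0
        else np.zeros_like(q)
        for R in radii
    ])
    V = _sphere_volume(radii)
    amp = contrasts[0] * VA[0]
    amp0 = contrasts[0] * V[0]
    for j in range(1, len(radii)):
        amp = amp + contrasts[j] * (VA[j] - VA[j - 1])
        amp0 = amp0 + contrasts[j] * (V[j] - V[j - 1])
    if amp0 == 0:
        if params.validate:
            raise InvalidParameterError("total excess scattering length is zero")
        amp0 = 1e-30  # let a bounded optimizer see huge residuals and back off
    P = (amp / amp0) ** 2
    return params.scale * P + params.background


_DEFAULT_BETA_NODES = 128
_beta_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _beta_quadrature(n_nodes):
    """Gauss–Legendre nodes/weights on [0, pi/2] including the sin(b) Jacobian."""
    if n_nodes not in _beta_cache:
        x, w = leggauss(n_nodes)
        beta = 0.25 * np.pi * (x + 1.0)
        weight = 0.25 * np.pi * w * np.sin(beta)
        _beta_cache[n_nodes] = (beta, weight)
    return _beta_cache[n_nodes]


def stacked_cylinder_intensity(q_grid, params: StackedCylinderParams,
                               n_beta=_DEFAULT_BETA_NODES):
    """Intensity a*P(q)+b of contiguously stacked cylinders, P(0) = 1.

    Coherent sum over cylinders of contrast * volume * amplitude * phase,
    with the phase factor exp(i q cos(b) d_j) carrying the center-to-center
    offset d_j of cylinder j from cylinder 1; orientationally averaged over
    beta in [0, pi/2] with sin(b) weight by Gauss–Legendre quadrature.
    """
    q = np.asarray(q_grid, dtype=float)
    L = np.asarray(params.lengths, dtype=float)
    contrasts = np.array([1.0, *params.rel_contrasts], dtype=float)
    n_c = len(L)
    volumes = np.pi * params.R**2 * L
    # center-to-center distance of cylinder j from cylinder 1
    d = np.zeros(n_c)
    for j in range(1, n_c):
        d[j] = L[0] / 2.0 + L[1:j].sum() + L[j] / 2.0

    beta, wgt = _beta_quadrature(n_beta)
    sinb = np.sin(beta)[None, :]
    cosb = np.cos(beta)[None, :]
    qc = q[:, None]

    amp = np.zeros((len(q), len(beta)), dtype=complex)
    for j in range(n_c):
        radial = _bessel_term(qc * params.R * sinb)
        axial = _sinc(qc * L[j] * cosb / 2.0)
        phase = np.exp(1j * qc * cosb * d[j])
        amp += contrasts[j] * volumes[j] * radial * axial * phase

    # integral of sin(b) over [0, pi/2] is 1, so P(0) normalizes exactly
    norm = (contrasts * volumes).sum() ** 2
    if norm == 0:
        if params.validate:
            raise InvalidParameterError("total excess scattering length is zero")
        norm = 1e-60
    P = (np.abs(amp) ** 2 @ wgt) / norm
    return params.scale * P + params.background


def hardsphere_structure_factor(q_grid, R_hs, eta):
    """Percus–Yevick structure factor for hard spheres.

    Parameters: hard-sphere radius R_hs [A] and volume fraction eta.
    S(q) -> 1 at large q; S(0) = (1-eta)^4/(1+2 eta)^2.
    """
    if not 0.0 <= eta < 0.74:
        raise InvalidParameterError(f"volume fraction out of range: {eta}")
    if R_hs <= 0:
        raise InvalidParameterError("hard-sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    if eta == 0.0:
        return np.ones_like(q)
    x = 2.0 * q * R_hs
    al = (1.0 + 2.0 * eta) ** 2 / (1.0 - eta) ** 4
    be = -6.0 * eta * (1.0 + eta / 2.0) ** 2 / (1.0 - eta) ** 4
    ga = eta * al / 2.0
    small = np.abs(x) < 0.05
    xs = np.where(small, 1.0, x)
    sx, cx = np.sin(xs), np.cos(xs)
    G = (al * (sx - xs * cx) / xs**2
         + be * (2.0 * xs * sx + (2.0 - xs**2) * cx - 2.0) / xs**3
         + ga * (-(xs**4) * cx
                 + 4.0 * ((3.0 * xs**2 - 6.0) * cx
                          + (xs**3 - 6.0 * xs) * sx + 6.0)) / xs**5)
    S = 1.0 / (1.0 + 24.0 * eta * G / xs)
    S0 = (1.0 - eta) ** 4 / (1.0 + 2.0 * eta) ** 2
    return np.where(small, S0, S)


def mixture_intensity(q_grid, I_comp1, I_comp2, params: MixtureParams):
    """s * (f_sym * I_1 + (1 - f_sym) * I_2) on a shared q grid."""
    I1 = np.asarray(I_comp1, dtype=float)
    I2 = np.asarray(I_comp2, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if I1.shape != q.shape or I2.shape != q.shape:
        raise GridMismatchError("component curves must share the q grid")
    return params.scale * (params.f_sym * I1 + params.f_asym * I2) \
        + params.background


# ---------------------------------------------------------------------------
# resolution smearing
# ---------------------------------------------------------------------------

def smear_model(q_grid, model_evaluator: Callable, sigma_q,
                width=3.0, oversample=5):
    """Gaussian q-resolution smearing of a model curve.

    At each q_i the model is averaged over q' ~ N(q_i, sigma_q_i) with the
    kernel truncated at +-``width`` sigma (and at q' > 0) and renormalized
    over its support.  Points with sigma_q_i = 0 are returned unsmeared.
    """
    q = np.asarray(q_grid, dtype=float)
    sq = np.broadcast_to(np.asarray(sigma_q, dtype=float), q.shape).copy()
    if np.any(sq < 0):
        raise InvalidParameterError("sigma_q must be non-negative")
    out = np.empty_like(q)
    zero = sq == 0
    if zero.any():
        out[zero] = model_evaluator(q[zero])
    if (~zero).any():
        qi = q[~zero]
        si = sq[~zero]
        n_nodes = 2 * int(np.ceil(width * oversample)) + 1
        offsets = np.linspace(-width, width, n_nodes)
        qp = qi[:, None] + si[:, None] * offsets[None, :]
        w = np.exp(-0.5 * offsets**2)[None, :] * np.ones_like(qp)
        valid = qp > 0
        w = np.where(valid, w, 0.0)
        qp_safe = np.where(valid, qp, qi[:, None])
        vals = model_evaluator(qp_safe.ravel()).reshape(qp_safe.shape)
        out[~zero] = (w * vals).sum(axis=1) / w.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# fit-facing model classes (parameter vectors, per-dataset evaluation)
# ---------------------------------------------------------------------------

@dataclass
class ScatteringModel:
    """A named intensity model over an ordered parameter vector.

    Subclasses define the layout of the parameter vector for ``n_datasets``
    simultaneously fitted curves (shared structural parameters first, then
    one block of nuisance parameters per dataset) and evaluate the intensity
    of dataset ``j`` at parameters ``x``.
    """

    name: str = ""
    n_datasets: int = 1

    @property
    def param_names(self) -> list[str]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def structural_indices(self) -> list[int]:
        """Indices of the geometric parameters entering the accuracy metric."""
        raise NotImplementedError

    def eval_dataset(self, j: int, q, x) -> np.ndarray:
        raise NotImplementedError


@dataclass
class CoreMultiShellModel(ScatteringModel):
    """Core + 3 shells; 4 shared radii plus (3 contrasts, scale, background)
    per dataset: K = 9 for one dataset, K = 14 for two.

    An optional fixed Percus–Yevick structure factor multiplies P(q); its
    radius and volume fraction are not refined.
    """

    name: str = "coreshell3"
    n_shells: int = 3
    hardsphere: tuple[float, float] | None = None  # (R_hs, eta), fixed

    @property
    def param_names(self):
        names = ["R_c"] + [f"R_{j}" for j in range(1, self.n_shells + 1)]
        for d in range(self.n_datasets):
            tag = f"_{d}" if self.n_datasets > 1 else ""
            names += [f"drho_{j}{tag}" for j in range(1, self.n_shells + 1)]
            names += [f"a{tag}", f"b{tag}"]
        return names

    @property
    def structural_indices(self):
        return list(range(self.n_shells + 1))

    def eval_dataset(self, j, q, x):
        x = np.asarray(x, dtype=float)
        ns = self.n_shells
        block = ns + 2
        off = (ns + 1) + j * block
        params = ShellSphereParams(
            R_c=x[0], shell_radii=x[1:ns + 1],
            rel_contrasts=x[off:off + ns],
            scale=x[off + ns], background=x[off + ns + 1],
            validate=False,
        )
        I = coreshell_intensity(q, params)
        if self.hardsphere is not None:
            I = (I - params.background) * self._sq(q) + params.background
        return I

    def _sq(self, q):
        """Fixed structure factor, cached per q grid."""
        key = (len(q), float(q[0]), float(q[-1]))
        cache = getattr(self, "_sq_cache", None)
        if cache is None or cache[0] != key:
            R_hs, eta = self.hardsphere
            self._sq_cache = (key, hardsphere_structure_factor(q, R_hs, eta))
        return self._sq_cache[1]

    def eval_dataset_grad(self, j, q, x):
        """Intensity and its analytic Jacobian d I / d x (shape M x K).

        The amplitude is F(q) = sum_m g_m V(R_m) A(q R_m) over the boundary
        radii R_m, with boundary coefficients g from the shell contrasts;
        d(V A)/dR = 4 pi R sin(qR)/q gives exact radius derivatives.
        """
        x = np.asarray(x, dtype=float)
        q = np.asarray(q, dtype=float)
        ns = self.n_shells
        block = ns + 2
        off = (ns + 1) + j * block
        radii = x[:ns + 1]
        c = x[off:off + ns]
        a, b = x[off + ns], x[off + ns + 1]
        # boundary coefficients: g_0 = 1 - c_1, g_m = c_m - c_{m+1}, g_ns = c_ns
        g = np.empty(ns + 1)
        g[0] = 1.0 - c[0]
        g[1:ns] = c[:ns - 1] - c[1:]
        g[ns] = c[-1]

        V = 4.0 * np.pi * radii**3 / 3.0
        A = np.stack([sphere_amplitude(q, R) if R > 0 else np.zeros_like(q)
                      for R in radii])           # (ns+1, M)
        VA = V[:, None] * A
        F = g @ VA
        F0 = float(g @ V)
        if F0 == 0:
            F0 = 1e-30
        P = (F / F0) ** 2
        S = self._sq(q) if self.hardsphere is not None else 1.0
        I = a * P * S + b

        K = self.n_params
        J = np.zeros((len(q), K))
        two_a_S = 2.0 * a * (F / F0) * (np.asarray(S) if self.hardsphere
                                        else 1.0)
        # radii (shared): d(VA)/dR = 4 pi R sin(qR)/q ; dV/dR = 4 pi R^2
        for m in range(ns + 1):
            R = radii[m]
            dVA = 4.0 * np.pi * R**2 * _sinc(q * R)   # = 4 pi R sin(qR)/q
            dV = 4.0 * np.pi * R**2
            J[:, m] = two_a_S * g[m] * (dVA * F0 - F * dV) / F0**2
        # contrasts of this dataset: dF/dc_k = VA_k - VA_{k-1}
        for k in range(ns):
            dF = VA[k + 1] - VA[k]
            dF0 = V[k + 1] - V[k]
            J[:, off + k] = two_a_S * (dF * F0 - F * dF0) / F0**2
        J[:, off + ns] = P * (np.asarray(S) if self.hardsphere else 1.0)
        J[:, off + ns + 1] = 1.0
        return I, J


@dataclass
class StackedCylinderModel(ScatteringModel):
    """Three stacked cylinders of common radius; shared (R, L1..L3) plus
    (2 relative contrasts, scale, background) per dataset."""

    name: str = "stackedcyl3"
    n_cyl: int = 3
    n_beta: int = _DEFAULT_BETA_NODES

    @property
    def param_names(self):
        names = ["R"] + [f"L_{j}" for j in range(1, self.n_cyl + 1)]
        for d in range(self.n_datasets):
            tag = f"_{d}" if self.n_datasets > 1 else ""
            names += [f"drho_{j}{tag}" for j in range(2, self.n_cyl + 1)]
            names += [f"a{tag}", f"b{tag}"]
        return names

    @property
    def structural_indices(self):
        return list(range(self.n_cyl + 1))

    def eval_dataset(self, j, q, x):
        x = np.asarray(x, dtype=float)
        nc = self.n_cyl
        block = (nc - 1) + 2
        off = (nc + 1) + j * block
        params = StackedCylinderParams(
            R=x[0], lengths=x[1:nc + 1],
            rel_contrasts=x[off:off + nc - 1],
            scale=x[off + nc - 1], background=x[off + nc],
            validate=False,
        )
        return stacked_cylinder_intensity(q, params, n_beta=self.n_beta)


@dataclass
class MixtureModel(ScatteringModel):
    """Two tabulated component curves mixed as s*(I_1 + r*I_2)/(1 + r).

    Fit parameters are the stoichiometric ratio r = f_2/f_1 and the overall
    scale s; the component fraction is f_1 = 1/(1+r).  The same r and s are
    shared across datasets, with one tabulated component pair per dataset.
    """

    name: str = "mixture"
    components: Sequence[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def param_names(self):
        return ["ratio", "s"]

    @property
    def structural_indices(self):
        return [0]

    def eval_dataset(self, j, q, x):
        I1, I2 = self.components[j]
        r, s = float(x[0]), float(x[1])
        f1 = 1.0 / (1.0 + r)
        return mixture_intensity(q, I1, I2, MixtureParams(f_sym=f1, scale=s))


MODEL_REGISTRY: dict[str, type] = {
    "coreshell3": CoreMultiShellModel,
    "stackedcyl3": StackedCylinderModel,
    "mixture": MixtureModel,
}


def get_model(name: str, n_datasets: int = 1, **kwargs) -> ScatteringModel:
    """Instantiate a registered model by name."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(n_datasets=n_datasets, **kwargs)
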