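"""Synthetic SAXS-like and SANS-like datasets with an empirical error model.

The simulator draws each intensity point from a normal distribution centred
on the theoretical curve, with standard deviations from a counting-statistics
style empirical model (sample + buffer counts with a 1/q pixel-statistics
term).  A noise factor inflates the true variance before sampling, and a
separate mis-scaling factor corrupts the *reported* errors after sampling,
so that reported uncertainties no longer reflect the actual fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "NoiseSpec",
    "Curve",
    "SAXS_NOISE",
    "SANS_NOISE",
    "make_qgrid",
    "sedlak_sigma",
    "sample_curve",
    "misscale_errors",
    "synth_sigma_q",
    "simulate_dataset",
]


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Empirical noise model settings.

    s : absolute-intensity scale (larger s = more counts = smaller relative
        errors); c : buffer-to-sample intensity constant in (0, 1);
    noise_factor : multiplier on the variance before sampling;
    error_misscale : multiplier applied to the reported sigma after sampling;
    k : global pixel-statistics constant of the 1/q term [A].
    """

    s: float = 100.0
    c: float = 0.85
    noise_factor: float = 1.0
    error_misscale: float = 1.0
    k: float = 2.0e3

    def __post_init__(self):
        if self.s <= 0 or not (0.0 < self.c < 1.0):
            raise InvalidParameterError("require s > 0 and 0 < c < 1")
        if self.noise_factor <= 0 or self.error_misscale <= 0 or self.k <= 0:
            raise InvalidParameterError(
                "noise_factor, error_misscale and k must be positive")


#: typical synchrotron SAXS condition (high flux, high signal-to-noise)
SAXS_NOISE = NoiseSpec(s=100.0, c=0.85)
#: typical SANS condition (lower flux, higher incoherent background)
SANS_NOISE = NoiseSpec(s=10.0, c=0.95)


@dataclass
class Curve:
    """One scattering dataset: q [1/A], I [1/cm], sigma [1/cm], optional
    q-resolution widths sigma_q [1/A]."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    sigma_q: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma_q is not None:
            self.sigma_q = np.asarray(self.sigma_q, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise InvalidParameterError("q, I, sigma must have equal length")
        if self.sigma_q is not None and self.sigma_q.shape != self.q.shape:
            raise InvalidParameterError("sigma_q length mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise InvalidParameterError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise InvalidParameterError("all sigma must be positive")

    @property
    def M(self) -> int:
        return len(self.q)


def make_qgrid(qmin, qmax, M):
    """M uniformly spaced q values from qmin to qmax inclusive."""
    if not 0 < qmin < qmax:
        raise InvalidParameterError("require 0 < qmin < qmax")
    if M < 2:
        raise InvalidParameterError("need at least two grid points")
    return np.linspace(qmin, qmax, int(M))


def sedlak_sigma(q, I_model, noise: NoiseSpec):
    """Point-wise standard deviations from the empirical counting model.

    The model curve is normalized and scaled to I_s(q) = s*I_model(q)/I(0)
    (I(0) taken at the smallest simulated q, background included); then

        sigma_s(q_i) = sqrt( [I_s(q_i) + 2c/(1-c) * I_s(q_i)] / (k q_i) )

    mapped back to absolute units and inflated by sqrt(noise_factor).

    The bracket is the propagated counting noise of buffer subtraction when
    the buffer contributes a constant fraction c of the total sample
    intensity at every q (sample counts + buffer counts, I_b = c/(1-c) *
    I_s), and the 1/(k q) factor models the number of detector pixels
    averaged in the q bin.  The global constant k [A] sets the overall
    exposure; see the methods note for its calibration.
    """
    q = np.asarray(q, dtype=float)
    I_model = np.asarray(I_model, dtype=float)
    if np.any(q <= 0):
        raise InvalidParameterError("q must be strictly positive")
    if np.any(I_model < 0):
        raise InvalidParameterError("model intensity must be non-negative")
    I0 = I_model[0]
    I_s = noise.s * I_model / I0
    buffer_factor = 1.0 + 2.0 * noise.c / (1.0 - noise.c)
    sigma_s = np.sqrt(I_s * buffer_factor / (noise.k * q))
    sigma = sigma_s * I0 / noise.s
    return np.sqrt(noise.noise_factor) * sigma


def sample_curve(q, I_model, sigma, seed=None, label="") -> Curve:
    """Draw I_i ~ Normal(I_model_i, sigma_i) independently per point."""
    rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    I_model = np.asarray(I_model, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise InvalidParameterError("sampling sigma must be positive")
    I = rng.normal(I_model, sigma)
    return Curve(q=q, I=I, sigma=sigma.copy(), label=label)


def misscale_errors(curve: Curve, m: float) -> Curve:
    """Multiply the *reported* sigma by m, leaving intensities untouched."""
    if m <= 0:
        raise InvalidParameterError("mis-scaling factor must be positive")
    return Curve(q=curve.q.copy(), I=curve.I.copy(), sigma=m * curve.sigma,
                 sigma_q=None if curve.sigma_q is None else curve.sigma_q.copy(),
                 label=curve.label)


def synth_sigma_q(q, relative_resolution=0.05, base_width=5.0e-4,
                  multiplier=1.0):
    """Smooth synthetic q-resolution column, affine in q.

    Emulates the typical growth of the instrumental q width with q; the
    multiplier hook reproduces deliberately exaggerated resolution
    conditions (x2, x3).
    """
    if relative_resolution < 0 or base_width < 0 or multiplier < 0:
        raise InvalidParameterError("resolution parameters must be >= 0")
    q = np.asarray(q, dtype=float)
    return multiplier * (base_width + relative_resolution * q)


def simulate_dataset(model_eval: Callable, qmin, qmax, M, noise: NoiseSpec,
                     sigma_q=None, seed=None, label="") -> Curve:
    """Simulate one dataset: theory (smeared if sigma_q given) -> errors ->
    normal sampling -> optional error mis-scaling.

    ``model_eval`` maps a q array to absolute intensities a*P(q)+b.  The
    sigma_q used for simulation is attached to the returned Curve so the
    same resolution enters the subsequent fit.
    """
    from .models import smear_model  # local import to avoid cycle at import time

    q = make_qgrid(qmin, qmax, M)
    if sigma_q is not None:
        sigma_q = np.broadcast_to(np.asarray(sigma_q, dtype=float), q.shape)
        I_model = smear_model(q, model_eval, sigma_q)
    else:
        I_model = model_eval(q)
    sigma = sedlak_sigma(q, I_model, noise)
    curve = sample_curve(q, I_model, sigma, seed=seed, label=label)
    if sigma_q is not None:
        curve.sigma_q = np.array(sigma_q, dtype=float)
    if noise.error_misscale != 1.0:
        curve = misscale_errors(curve, noise.error_misscale)
    return curve
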