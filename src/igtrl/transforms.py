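"""Bounded parameter transforms shared by the generator, MLE and the sampler.

Every natural-scale model parameter lives in a finite interval (lo, hi).
Latent values are unconstrained reals mapped through the probit:

    natural = lo + (hi - lo) * Phi(z)

so subject-level variation can be modeled as normal on the latent scale
while draws always respect the bounds. The moments of the transformed
normal have closed forms (second moment via Owen's T), which is what the
cohort generator uses to calibrate latent hyperparameters to target
natural-scale means and SDs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t

from .models import EVL_BOUNDS, PVL_BOUNDS

PARAM_NAMES = {
    "evl": ("w", "phi", "c_evl"),
    "pvl_delta": ("alpha", "lam", "A", "c"),
    "pvl_decay": ("alpha", "lam", "A", "c"),
}


def param_bounds(model: str) -> list[tuple[float, float]]:
    table = EVL_BOUNDS if model == "evl" else PVL_BOUNDS
    return [table[name] for name in PARAM_NAMES[model]]


def to_natural(z: np.ndarray, bounds) -> np.ndarray:
    """Map latent values to the natural scale, per-parameter bounds applied
    along the last axis."""
    z = np.asarray(z, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * ndtr(z)


def to_latent(x: np.ndarray, bounds) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return ndtri((x - lo) / (hi - lo))


def transformed_normal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """E[lo + (hi-lo)·Phi(mu + sigma·Z)] for Z ~ N(0,1)."""
    return lo + (hi - lo) * float(ndtr(mu / np.sqrt(1.0 + sigma**2)))


def transformed_normal_sd(mu: float, sigma: float, lo: float, hi: float) -> float:
    """SD of lo + (hi-lo)·Phi(mu + sigma·Z).

    Uses E[Phi(mu+sigma Z)^2] = BvN(h, h; rho) with h = mu/sqrt(1+sigma^2)
    and rho = sigma^2/(1+sigma^2), evaluated via Owen's T.
    """
    h = mu / np.sqrt(1.0 + sigma**2)
    p = float(ndtr(h))
    second = p - 2.0 * float(owens_t(h, 1.0 / np.sqrt(1.0 + 2.0 * sigma**2)))
    var = max(second - p * p, 0.0)
    return (hi - lo) * np.sqrt(var)


def calibrate_latent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Solve for latent (mu, sigma) whose probit-transformed normal has the
    given natural-scale mean and SD.

    The mean pins mu given sigma (mu = Phi^{-1}(p)·sqrt(1+sigma^2)); sigma
    is then found by root-finding on the closed-form SD. Raises if the
    target SD is infeasible for a bounded variable with that mean.
    """
    width = hi - lo
    p = (mean - lo) / width
    if not 0.0 < p < 1.0:
        raise ValueError(f"target mean {mean} outside ({lo}, {hi})")
    if sd < 0:
        raise ValueError("target sd must be >= 0")
    if sd == 0:
        return float(ndtri(p)), 0.0
    max_sd = width * np.sqrt(p * (1.0 - p))
    if sd >= max_sd:
        raise ValueError(
            f"target sd {sd} infeasible for a bounded variable with mean {mean} "
            f"on ({lo}, {hi}) (max {max_sd:.4g})"
        )

    zp = float(ndtri(p))

    def gap(sigma: float) -> float:
        mu = zp * np.sqrt(1.0 + sigma**2)
        return transformed_normal_sd(mu, sigma, lo, hi) - sd

    # SD of the transform is 0 at sigma=0 and approaches the two-point
    # bound as sigma -> inf, so the root is bracketed.
    hi_s = 1.0
    while gap(hi_s) < 0 and hi_s < 1e4:
        hi_s *= 2.0
    sigma = brentq(gap, 1e-9, hi_s, xtol=1e-12)
    mu = zp * np.sqrt(1.0 + sigma**2)
    return float(mu), float(sigma)
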