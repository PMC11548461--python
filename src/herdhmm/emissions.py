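"""Per-state emission laws for the trajectory metrics.

A behavioural state emits, every 30-min step, a step length and a turning
angle.  Step lengths follow a zero-inflated positive law: a point mass zeta
at exactly zero (collar motionless below GPS resolution) mixed with a
continuous density on (0, inf).  Two continuous families are provided:

``truncnorm``
    A normal law truncated to (0, inf) and renormalised, parameterised by the
    *untruncated* mean and SD so printed (mu, sigma) values keep their
    meaning.  This is the default family.
``gamma``
    A gamma law with the same mean/SD moment parameterisation.

Turning angles follow the von Mises circular law with mean direction
``mu_angle`` and concentration ``kappa`` (kappa = 0 is the circular uniform).
"""

from __future__ import annotations

import numpy as np
from scipy import special

STEP_ZERO_TOL_M = 1e-6  # a computed distance below this counts as "exactly zero"

_LOG_2PI = np.log(2.0 * np.pi)


def _check_family(family: str) -> None:
    if family not in ("truncnorm", "gamma"):
        raise ValueError(f"unknown step-law family: {family!r}")


def positive_step_log_density(x, mu, sigma, family="truncnorm"):
    """Log density of the continuous (positive) part of the step law."""
    _check_family(family)
    x = np.asarray(x, dtype=float)
    if family == "truncnorm":
        z = (x - mu) / sigma
        # P(X > 0) = Phi(mu/sigma) for the untruncated normal
        log_norm = special.log_ndtr(mu / sigma)
        return -np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z - log_norm
    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    return (
        (shape - 1.0) * np.log(x)
        - x / scale
        - special.gammaln(shape)
        - shape * np.log(scale)
    )


def step_log_density(x, mu, sigma, zeta, family="truncnorm"):
    """Log density/mass of the zero-inflated step law.

    Returns log(zeta) where x is (numerically) zero and
    log(1 - zeta) + log f(x) elsewhere.  Negative steps are a domain error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("step lengths must be non-negative")
    is_zero = x < STEP_ZERO_TOL_M
    with np.errstate(divide="ignore", invalid="ignore"):
        cont = positive_step_log_density(np.where(is_zero, 1.0, x), mu, sigma, family)
        out = np.where(
            is_zero,
            np.log(zeta) if zeta > 0 else -np.inf,
            np.log1p(-zeta) + cont,
        )
    return out


def angle_log_density(theta, mu_angle, kappa):
    """Von Mises log density on (-pi, pi].

    NaN entries (missing angles) are propagated as NaN; callers treat them as
    a zero contribution to the joint log density.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    theta = np.asarray(theta, dtype=float)
    # log I0(kappa) via the exponentially scaled Bessel function, stable for
    # large concentrations
    log_i0 = np.log(special.i0e(kappa)) + kappa
    return kappa * np.cos(theta - mu_angle) - _LOG_2PI - log_i0


def sample_steps(rng: np.random.Generator, n, mu, sigma, zeta, family="truncnorm"):
    """Draw step lengths from the zero-inflated law."""
    _check_family(family)
    if family == "truncnorm":
        # rejection-free draw via inverse CDF on the truncated region
        lo = special.ndtr(-mu / sigma)  # P(X <= 0)
        u = rng.uniform(lo, 1.0, size=n)
        x = mu + sigma * special.ndtri(u)
        x = np.maximum(x, STEP_ZERO_TOL_M * 10)
    else:
        shape = (mu / sigma) ** 2
        scale = sigma**2 / mu
        x = rng.gamma(shape, scale, size=n)
    if zeta > 0:
        x[rng.uniform(size=n) < zeta] = 0.0
    return x


def sample_angles(rng: np.random.Generator, n, mu_angle, kappa):
    """Draw turning angles from the von Mises law, wrapped to (-pi, pi]."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    theta = rng.vonmises(mu_angle, kappa, size=n) if kappa > 0 else rng.uniform(-np.pi, np.pi, size=n)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return out
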