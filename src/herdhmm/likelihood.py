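"""Forward log likelihood and Viterbi decoding for the behaviour model.

Independent segments contribute additively to the joint log likelihood, each
restarting from the shared initial distribution Pi.  Per-observation
emission density is the product of the step density and, where the turning
angle is defined, the angle density; missing angles contribute a factor 1.

Observation alignment within a segment of n fixes: observation t
(t = 0..n-2) carries step t and, for t >= 1, the turning angle at the fix
joining steps t-1 and t.  The first observation of a segment never has an
angle.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .emissions import angle_log_density, step_log_density
from .model import HmmModel
from .trajectory import StepAngleSeries

_LOG_EPS = -1e300


def emission_log_densities(model: HmmModel, series: StepAngleSeries) -> np.ndarray:
    """(T, S) matrix of per-observation, per-state log emission densities."""
    T = series.n_obs
    out = np.zeros((T, model.n_states))
    angles = np.full(T, np.nan)
    if T > 1:
        angles[1:] = series.angles
    have_angle = np.isfinite(angles)
    for s, e in enumerate(model.emissions):
        col = step_log_density(series.steps, e.mu, e.sigma, e.zeta, model.step_family)
        if have_angle.any():
            col = col.copy()
            col[have_angle] += angle_log_density(angles[have_angle], e.mu_angle, e.kappa)
        out[:, s] = col
    return np.nan_to_num(out, nan=_LOG_EPS, neginf=_LOG_EPS)


def _gammas_for(model: HmmModel, series: StepAngleSeries) -> np.ndarray:
    C = len(model.covariates)
    T = series.n_obs
    if C == 0:
        g = model.transitions.matrix()
        return np.broadcast_to(g, (T, *g.shape)).copy()
    Z = np.column_stack([series.covariates[name] for name in model.covariates])
    return model.transitions.matrices(Z)


def log_likelihood(model: HmmModel, data) -> float:
    """Joint forward log likelihood over one or more segments."""
    if isinstance(data, StepAngleSeries):
        data = [data]
    if not data:
        raise ValueError("no data")
    ll = 0.0
    pi0 = np.asarray(model.pi0, dtype=float)
    for series in data:
        if series.n_obs == 0:
            continue
        log_b = emission_log_densities(model, series)
        gammas = _gammas_for(model, series)
        ll += _kernels.forward_loglik(log_b, gammas, pi0)
    return float(ll)


def viterbi(model: HmmModel, data) -> list[np.ndarray]:
    """Most probable state path per segment (list of int arrays)."""
    single = isinstance(data, StepAngleSeries)
    if single:
        data = [data]
    paths = []
    with np.errstate(divide="ignore"):
        log_pi0 = np.log(np.asarray(model.pi0, dtype=float))
    log_pi0 = np.maximum(log_pi0, _LOG_EPS)
    for series in data:
        if series.n_obs == 0:
            paths.append(np.empty(0, dtype=np.int64))
            continue
        log_b = emission_log_densities(model, series)
        with np.errstate(divide="ignore"):
            log_g = np.log(_gammas_for(model, series))
        log_g = np.maximum(log_g, _LOG_EPS)
        paths.append(_kernels.viterbi_path(log_b, log_g, log_pi0))
    return paths
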