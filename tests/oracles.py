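"""Independent brute-force oracles for the HMM recursions.

Emission densities are computed directly with scipy.stats (truncated normal
and von Mises), and path probabilities by exhaustive enumeration over all
S^T state sequences, so these share no code with the package's forward and
Viterbi implementations.
"""

import itertools

import numpy as np
from scipy import stats
from scipy.special import logsumexp

import herdhmm as hh


def random_toy_model(rng, n_states, with_zero_inflation=True):
    """A random small model for oracle-equivalence sweeps."""
    ems = []
    for _ in range(n_states):
        ems.append(
            hh.EmissionParams(
                mu=rng.uniform(10, 800),
                sigma=rng.uniform(10, 400),
                zeta=rng.uniform(0.0, 0.3) if with_zero_inflation else 0.0,
                mu_angle=rng.uniform(-np.pi, np.pi),
                kappa=rng.uniform(0.0, 5.0),
            )
        )
    gamma = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    pi0 = rng.dirichlet(np.ones(n_states))
    return hh.HmmModel(
        n_states=n_states,
        emissions=ems,
        transitions=hh.TransitionStructure.from_matrix(gamma),
        pi0=pi0,
    )


def random_toy_series(rng, n_obs, zero_prob=0.15):
    steps = rng.uniform(1.0, 900.0, size=n_obs)
    steps[rng.uniform(size=n_obs) < zero_prob] = 0.0
    angles = rng.uniform(-np.pi, np.pi, size=max(n_obs - 1, 0))
    if n_obs > 1:
        angles[rng.uniform(size=n_obs - 1) < 0.2] = np.nan
    return hh.StepAngleSeries("toy", steps, angles)


def emission_logpdf_scipy(model, series):
    """(T, S) log emission matrix via scipy distributions."""
    T = series.n_obs
    angles = np.full(T, np.nan)
    if T > 1:
        angles[1:] = series.angles
    out = np.zeros((T, model.n_states))
    for s, e in enumerate(model.emissions):
        a = -e.mu / e.sigma
        for t in range(T):
            x = series.steps[t]
            if x < 1e-6:
                lp = np.log(e.zeta) if e.zeta > 0 else -np.inf
            else:
                lp = np.log1p(-e.zeta) + stats.truncnorm.logpdf(
                    x, a, np.inf, loc=e.mu, scale=e.sigma
                )
            if np.isfinite(angles[t]):
                lp += stats.vonmises.logpdf(angles[t], e.kappa, loc=e.mu_angle)
            out[t, s] = lp
    return out


def brute_force_loglik(model, series):
    """Log likelihood by exhaustive summation over all state paths."""
    log_b = emission_logpdf_scipy(model, series)
    T, S = log_b.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi0)
        log_g = np.log(model.transitions.matrix())
    terms = []
    for path in itertools.product(range(S), repeat=T):
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_g[path[t - 1], path[t]] + log_b[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def brute_force_viterbi(model, series):
    """Most probable path by exhaustive argmax; ties to the lexicographically
    smallest path, matching a lowest-state-index tie rule."""
    log_b = emission_logpdf_scipy(model, series)
    T, S = log_b.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi0)
        log_g = np.log(model.transitions.matrix())
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_g[path[t - 1], path[t]] + log_b[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp
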