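"""Maximum-likelihood fitting of the behaviour model.

The negative log likelihood is minimised by a quasi-Newton method (L-BFGS-B
with finite-difference gradients) over unconstrained working parameters:
log for mu, sigma and kappa; logit for the zero-inflation mass; the angle
mean enters the density only through cos(theta - mu_angle), so its working
parameter is the raw angle (periodic, hence wrap-safe); transition entries
through the row-wise multinomial logit; the initial distribution through a
softmax with state 0 as reference.

Because the likelihood surface is multimodal, :func:`multistart_fit` draws
initial emission parameters uniformly within per-state sampling limits,
fits each start, relabels every result canonically (ascending mean step
length) and returns the best, together with a consensus summary: the
fraction of restarts whose log likelihood lands within 0.5 log-units of the
best, the practical criterion for "same optimum".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from . import _kernels
from .emissions import STEP_ZERO_TOL_M, angle_log_density, positive_step_log_density
from .model import EmissionParams, FitResult, HmmModel, TransitionStructure, canonicalize
from .trajectory import StepAngleSeries

_LOG_EPS = -1e300
_BIG = 1e12


@dataclass
class FitOptions:
    maxiter: int = 1000
    gtol: float = 1e-6
    ftol: float = 1e-8


@dataclass
class SamplingBounds:
    """Per-state uniform sampling limits for multistart initialisation.

    Arrays have one (lo, hi) pair per state.  ``zeta_init`` holds fixed
    starting values for the zero-inflation mass (not sampled).  Bounds
    constrain initialisation only — never the optimizer.
    """

    mu: np.ndarray
    sigma: np.ndarray
    mu_angle: np.ndarray
    kappa: np.ndarray
    zeta_init: np.ndarray

    def __post_init__(self):
        for name in ("mu", "sigma", "mu_angle", "kappa"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or np.any(arr[:, 0] > arr[:, 1]):
                raise ValueError(f"{name} bounds must be well-ordered (lo <= hi) pairs")
            setattr(self, name, arr)
        self.zeta_init = np.asarray(self.zeta_init, dtype=float)

    @property
    def n_states(self) -> int:
        return self.mu.shape[0]


def table1_bounds(p0: float) -> SamplingBounds:
    """Sampling limits used for the 3-state Sahel cattle model.

    Zero-inflation starts at the dataset zero-step fraction p0 for the
    resting state and p0/100 for the mobile states.
    """
    return SamplingBounds(
        mu=[(5, 100), (50, 250), (100, 1000)],
        sigma=[(5, 100), (50, 500), (100, 1000)],
        mu_angle=[(-3, 3), (-3, 3), (-0.5, 0.5)],
        kappa=[(0.1, 1), (1.5, 5), (1, 15)],
        zeta_init=[p0, p0 / 100, p0 / 100],
    )


def quantile_bounds(data, n_states: int) -> SamplingBounds:
    """Data-driven sampling limits for an arbitrary state count.

    Non-zero steps are split into n_states quantile bands; each state's mu
    and sigma ranges bracket its band.  Angle means are left wide; the top
    (fastest) state gets a higher concentration range, mirroring how a
    travelling state looks in practice.
    """
    steps = np.concatenate([s.steps for s in _as_list(data)])
    nz = steps[steps >= STEP_ZERO_TOL_M]
    if nz.size == 0:
        raise ValueError("no non-zero steps in data")
    p0 = 1.0 - nz.size / steps.size
    mu, sg, ma, kp = [], [], [], []
    for i in range(n_states):
        q = np.quantile(nz, (i + 0.5) / n_states)
        q = max(q, 1.0)
        mu.append((0.4 * q, 2.5 * q))
        sg.append((0.4 * q, 2.5 * q))
        ma.append((-3, 3) if i < n_states - 1 else (-0.5, 0.5))
        kp.append((0.1, 2) if i < n_states - 1 else (0.5, 10))
    zeta = np.full(n_states, max(p0, 1e-8) / 100)
    zeta[0] = max(p0, 1e-8)
    return SamplingBounds(mu=mu, sigma=sg, mu_angle=ma, kappa=kp, zeta_init=zeta)


# ---------------------------------------------------------------------------
# working-parameter packing


def _as_list(data):
    return [data] if isinstance(data, StepAngleSeries) else list(data)


class _Packed:
    """Layout of the unconstrained working-parameter vector."""

    def __init__(self, n_states: int, covariates: tuple[str, ...]):
        s, c = n_states, len(covariates)
        self.S, self.C = s, c
        self.covariates = covariates
        self.n_beta = s * (s - 1) * (1 + c)
        self.size = 5 * s + self.n_beta + (s - 1)

    def pack(self, model: HmmModel) -> np.ndarray:
        S = self.S
        th = np.empty(self.size)
        em = model.emissions
        th[0:S] = [np.log(e.mu) for e in em]
        th[S:2 * S] = [np.log(e.sigma) for e in em]
        th[2 * S:3 * S] = [special.logit(np.clip(e.zeta, 1e-12, 1 - 1e-12)) for e in em]
        th[3 * S:4 * S] = [e.mu_angle for e in em]
        th[4 * S:5 * S] = [np.log(max(e.kappa, 1e-6)) for e in em]
        th[5 * S:5 * S + self.n_beta] = model.transitions.beta.ravel()
        if S > 1:
            p = np.clip(model.pi0, 1e-12, None)
            th[5 * S + self.n_beta:] = np.log(p[1:]) - np.log(p[0])
        return th

    def unpack(self, th: np.ndarray, centres: np.ndarray,
               step_family: str) -> HmmModel:
        S = self.S
        mu = np.exp(th[0:S])
        sigma = np.exp(th[S:2 * S])
        zeta = special.expit(th[2 * S:3 * S])
        mu_angle = -((-th[3 * S:4 * S] + np.pi) % (2 * np.pi) - np.pi)
        kappa = np.exp(th[4 * S:5 * S])
        beta = th[5 * S:5 * S + self.n_beta].reshape(S * (S - 1), 1 + self.C)
        if S > 1:
            logits = np.concatenate([[0.0], th[5 * S + self.n_beta:]])
            pi0 = np.exp(logits - logits.max())
            pi0 /= pi0.sum()
        else:
            pi0 = np.ones(1)
        return HmmModel(
            n_states=S,
            emissions=[
                EmissionParams(mu[i], sigma[i], float(zeta[i]), float(mu_angle[i]),
                               float(kappa[i]))
                for i in range(S)
            ],
            transitions=TransitionStructure(
                n_states=S, beta=beta, covariates=self.covariates, centres=centres
            ),
            pi0=pi0,
            step_family=step_family,
        )

    def box_bounds(self):
        S = self.S
        b = []
        b += [(np.log(1e-2), np.log(1e6))] * S          # log mu
        b += [(np.log(1e-2), np.log(1e6))] * S          # log sigma
        b += [(-30.0, 5.0)] * S                          # logit zeta
        b += [(-10.0, 10.0)] * S                         # mu_angle (periodic)
        b += [(np.log(1e-4), np.log(1e3))] * S           # log kappa
        b += [(-30.0, 30.0)] * self.n_beta               # transition logits
        b += [(-30.0, 30.0)] * (S - 1)                   # pi0 logits
        return b


class _Objective:
    """Precomputed data views + negative log likelihood of working params."""

    def __init__(self, data, covariates: tuple[str, ...], step_family: str,
                 n_states: int):
        data = _as_list(data)
        segs = []
        for s in data:
            if s.n_obs == 0:
                continue
            T = s.n_obs
            angles = np.full(T, np.nan)
            if T > 1:
                angles[1:] = s.angles
            Z = (np.column_stack([s.covariates[c] for c in covariates])
                 if covariates else np.zeros((T, 0)))
            segs.append((s.steps, angles, np.isfinite(angles), Z))
        if not segs:
            raise ValueError("no observations to fit")
        self.segs = segs
        self.covariates = covariates
        self.step_family = step_family
        self.packed = _Packed(n_states, covariates)
        allZ = np.vstack([Z for (_, _, _, Z) in segs])
        self.centres = allZ.mean(axis=0) if allZ.shape[1] else np.zeros(0)
        self.n_obs = sum(s[0].size for s in segs)
        self.zero_masks = [steps < STEP_ZERO_TOL_M for (steps, _, _, _) in segs]

    def _seg_log_b(self, model, steps, angles, have_angle, zero):
        S = model.n_states
        T = steps.size
        log_b = np.empty((T, S))
        safe_steps = np.where(zero, 1.0, steps)
        for s_idx, e in enumerate(model.emissions):
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                cont = positive_step_log_density(
                    safe_steps, e.mu, e.sigma, self.step_family
                )
                col = np.where(
                    zero,
                    np.log(e.zeta) if e.zeta > 0 else -np.inf,
                    np.log1p(-e.zeta) + cont,
                )
                col = col.copy()
                col[have_angle] += angle_log_density(
                    angles[have_angle], e.mu_angle, e.kappa
                )
            log_b[:, s_idx] = col
        return np.nan_to_num(log_b, nan=_LOG_EPS, neginf=_LOG_EPS, posinf=_BIG)

    def _seg_gammas(self, model, T, Z):
        S = model.n_states
        if not self.covariates:
            g = model.transitions.matrix()
            return np.ascontiguousarray(np.broadcast_to(g, (T, S, S)))
        return model.transitions.matrices(Z)

    def nll(self, th: np.ndarray) -> float:
        try:
            model = self.packed.unpack(th, self.centres, self.step_family)
        except (ValueError, FloatingPointError):
            return _BIG
        total = 0.0
        for (steps, angles, have_angle, Z), zero in zip(self.segs, self.zero_masks):
            log_b = self._seg_log_b(model, steps, angles, have_angle, zero)
            gammas = self._seg_gammas(model, steps.size, Z)
            ll = _kernels.forward_loglik(log_b, gammas, model.pi0)
            if not np.isfinite(ll):
                return _BIG
            total += ll
        return -total

    def nll_and_grad(self, th: np.ndarray):
        """Negative log likelihood and its analytic gradient.

        Posterior state probabilities from a forward-backward pass weight the
        per-observation emission-score terms; the transition gradient comes
        from the pairwise posteriors accumulated inside the kernel.
        """
        try:
            model = self.packed.unpack(th, self.centres, self.step_family)
        except (ValueError, FloatingPointError):
            return _BIG, np.zeros_like(th)
        S = model.n_states
        P = self.packed
        grad = np.zeros(P.size)
        g_beta = np.zeros((S * (S - 1), 1 + P.C))
        total = 0.0
        for (steps, angles, have_angle, Z), zero in zip(self.segs, self.zero_masks):
            log_b = self._seg_log_b(model, steps, angles, have_angle, zero)
            gammas = self._seg_gammas(model, steps.size, Z)
            zc = np.ascontiguousarray(Z - self.centres) if P.C else np.zeros(
                (steps.size, 0))
            ll, post, gb = _kernels.forward_backward(log_b, gammas, model.pi0, zc)
            if not np.isfinite(ll):
                return _BIG, np.zeros_like(th)
            total += ll
            g_beta += gb
            if S > 1:
                grad[5 * S + P.n_beta:] += post[0, 1:] - model.pi0[1:]
            pos = ~zero
            x = steps[pos]
            th_ang = angles[have_angle]
            for s_idx, e in enumerate(model.emissions):
                w = post[:, s_idx]
                wp = w[pos]
                if self.step_family == "truncnorm":
                    r = e.mu / e.sigma
                    ratio = np.exp(
                        -0.5 * r * r - 0.5 * np.log(2 * np.pi)
                        - special.log_ndtr(r)
                    )
                    zstd = (x - e.mu) / e.sigma
                    dmu = zstd / e.sigma - ratio / e.sigma
                    dsig = (zstd * zstd - 1.0) / e.sigma + ratio * e.mu / e.sigma**2
                else:
                    a = (e.mu / e.sigma) ** 2
                    th_sc = e.sigma**2 / e.mu
                    dlf_da = np.log(x) - np.log(th_sc) - special.digamma(a)
                    dlf_dth = x / th_sc**2 - a / th_sc
                    dmu = dlf_da * (2 * e.mu / e.sigma**2) + dlf_dth * (
                        -e.sigma**2 / e.mu**2)
                    dsig = dlf_da * (-2 * e.mu**2 / e.sigma**3) + dlf_dth * (
                        2 * e.sigma / e.mu)
                grad[s_idx] += e.mu * float(wp @ dmu)
                grad[S + s_idx] += e.sigma * float(wp @ dsig)
                grad[2 * S + s_idx] += float(
                    (1.0 - e.zeta) * w[zero].sum() - e.zeta * wp.sum()
                )
                wa = w[have_angle]
                if wa.size:
                    delta = th_ang - e.mu_angle
                    grad[3 * S + s_idx] += e.kappa * float(wa @ np.sin(delta))
                    bessel_ratio = special.i1e(e.kappa) / special.i0e(e.kappa)
                    grad[4 * S + s_idx] += e.kappa * float(
                        wa @ np.cos(delta) - wa.sum() * bessel_ratio
                    )
        grad[5 * S:5 * S + P.n_beta] = g_beta.ravel()
        return -total, -grad


def fit(data, init: HmmModel, opts: FitOptions | None = None) -> FitResult:
    """Quasi-Newton maximisation of the log likelihood from one start.

    The returned log likelihood never falls below the initial one: the best
    point seen during optimisation is retained even when the line search
    terminates elsewhere or the iteration cap is hit.
    """
    opts = opts or FitOptions()
    obj = _Objective(data, init.covariates, init.step_family, init.n_states)
    th0 = obj.packed.pack(init)
    best = {"f": obj.nll(th0), "x": th0.copy()}

    def f(th):
        v, g = obj.nll_and_grad(th)
        if v < best["f"]:
            best["f"] = v
            best["x"] = th.copy()
        return v, g

    res = optimize.minimize(
        f,
        th0,
        method="L-BFGS-B",
        jac=True,
        bounds=obj.packed.box_bounds(),
        options={"maxiter": opts.maxiter, "gtol": opts.gtol, "ftol": opts.ftol},
    )
    model = obj.packed.unpack(best["x"], obj.centres, init.step_family)
    return FitResult(
        model=model,
        loglik=-best["f"],
        n_iter=int(res.nit),
        converged=bool(res.success) and np.isfinite(best["f"]),
    )


@dataclass
class MultistartSummary:
    logliks: np.ndarray
    converged: np.ndarray
    consensus: float
    best_restart: int
    delta: float = 0.5


def draw_init(rng: np.random.Generator, bounds: SamplingBounds,
              covariates: tuple[str, ...] = (), centres=None,
              step_family: str = "truncnorm",
              self_stay: float = 0.8) -> HmmModel:
    """One uniform draw of initial emission parameters within bounds.

    Transitions start diagonal-dominant (self-transition ``self_stay``,
    off-diagonal mass spread evenly, zero covariate slopes) and pi0 uniform;
    the sampling limits apply to emission parameters only.
    """
    S = bounds.n_states
    em = []
    for i in range(S):
        em.append(
            EmissionParams(
                mu=rng.uniform(*bounds.mu[i]),
                sigma=rng.uniform(*bounds.sigma[i]),
                zeta=float(np.clip(bounds.zeta_init[i], 1e-10, 0.5)),
                mu_angle=rng.uniform(*bounds.mu_angle[i]),
                kappa=rng.uniform(*bounds.kappa[i]),
            )
        )
    C = len(covariates)
    if S > 1:
        off = (1.0 - self_stay) / (S - 1)
        beta0 = np.log(off / self_stay)
        beta = np.zeros((S * (S - 1), 1 + C))
        beta[:, 0] = beta0
    else:
        beta = np.zeros((0, 1 + C))
    return HmmModel(
        n_states=S,
        emissions=em,
        transitions=TransitionStructure(
            n_states=S, beta=beta, covariates=covariates,
            centres=np.zeros(C) if centres is None else np.asarray(centres, float),
        ),
        pi0=np.full(S, 1.0 / S),
        step_family=step_family,
    )


def multistart_fit(
    data,
    n_states: int,
    bounds: SamplingBounds | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    covariates: tuple[str, ...] = (),
    step_family: str = "truncnorm",
    opts: FitOptions | None = None,
) -> tuple[FitResult, MultistartSummary]:
    """Multistart maximum likelihood: best canonical model + consensus.

    ``bounds`` defaults to data-driven quantile limits (use
    :func:`table1_bounds` to reproduce the published 3-state limits).  Two
    restarts count as the same optimum when their canonical log likelihoods
    agree within 0.5 log-units.
    """
    data = _as_list(data)
    if bounds is None:
        bounds = quantile_bounds(data, n_states)
    if bounds.n_states != n_states:
        raise ValueError("bounds state count does not match n_states")
    rng = np.random.default_rng(seed)
    results: list[FitResult] = []
    errors: list[Exception] = []
    obj_centres = None
    for r in range(n_restarts):
        init = draw_init(rng, bounds, covariates=covariates,
                         centres=obj_centres, step_family=step_family)
        try:
            fr = fit(data, init, opts)
        except Exception as exc:  # keep going; aggregate at the end
            errors.append(exc)
            continue
        cmodel, _ = canonicalize(fr.model)
        results.append(
            FitResult(model=cmodel, loglik=fr.loglik, n_iter=fr.n_iter,
                      converged=fr.converged, restart_id=r, canonical=True)
        )
    if not results:
        raise RuntimeError(f"all {n_restarts} restarts failed: {errors[:3]!r}")
    lls = np.array([fr.loglik for fr in results])
    best_idx = int(np.argmax(lls))
    summary = MultistartSummary(
        logliks=lls,
        converged=np.array([fr.converged for fr in results]),
        consensus=float(np.mean(lls >= lls[best_idx] - 0.5)),
        best_restart=results[best_idx].restart_id,
    )
    return results[best_idx], summary
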