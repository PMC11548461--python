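"""Model containers: emission parameters, covariate-logit transitions, the
full N-state behaviour model, and fit-result bookkeeping.

The transition matrix Gamma uses a row-wise multinomial logit with the
diagonal as reference category: for row i and column j != i the linear
predictor is eta_ij = beta0_ij + beta_ij . (z - z_centre), and

    Gamma_ij = exp(eta_ij) / (1 + sum_{j' != i} exp(eta_ij'))
    Gamma_ii = 1          / (1 + sum_{j' != i} exp(eta_ij'))

so every row is a probability vector for any finite covariate value.
Covariates are centred with stored constants for numerical conditioning;
slopes are unchanged by the centring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np


@dataclass
class EmissionParams:
    """One state's emission law: zero-inflated step + von Mises angle.

    mu, sigma are the (untruncated) mean and SD of the step law in metres per
    30-min interval; zeta the zero-inflation mass; mu_angle the mean turning
    angle in (-pi, pi]; kappa the angular concentration.
    """

    mu: float
    sigma: float
    zeta: float
    mu_angle: float
    kappa: float

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.zeta < 1.0:
            raise ValueError("zeta must lie in [0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not -np.pi < self.mu_angle <= np.pi + 1e-12:
            raise ValueError("mu_angle must lie in (-pi, pi]")


@dataclass
class TransitionStructure:
    """Multinomial-logit transition parameters.

    ``beta`` has shape (S*(S-1), 1 + C): one row per off-diagonal entry of
    Gamma in row-major order (i ascending, then j != i ascending), columns
    are intercept followed by one slope per covariate.  ``covariates`` names
    the C covariates; ``centres`` holds the centring constants.
    """

    n_states: int
    beta: np.ndarray
    covariates: tuple[str, ...] = ()
    centres: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.centres = np.asarray(self.centres, dtype=float)
        s, c = self.n_states, len(self.covariates)
        if self.beta.shape != (s * (s - 1), 1 + c):
            raise ValueError(
                f"beta must have shape ({s * (s - 1)}, {1 + c}), got {self.beta.shape}"
            )
        if self.centres.size == 0:
            self.centres = np.zeros(c)
        if self.centres.shape != (c,):
            raise ValueError("centres must have one entry per covariate")

    @classmethod
    def from_matrix(cls, gamma: np.ndarray) -> "TransitionStructure":
        """Covariate-free structure whose Gamma(.) equals the given matrix."""
        gamma = np.asarray(gamma, dtype=float)
        s = gamma.shape[0]
        if gamma.shape != (s, s):
            raise ValueError("gamma must be square")
        if np.any(gamma < 0) or not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("gamma rows must be probability vectors")
        if np.any(np.diag(gamma) <= 0):
            raise ValueError("diagonal (reference) entries must be positive")
        # zero off-diagonals are representable only in the limit; clip far
        # below any probability that matters
        gclip = np.clip(gamma, 1e-300, None)
        beta = np.empty((s * (s - 1), 1))
        k = 0
        for i in range(s):
            for j in range(s):
                if j != i:
                    beta[k, 0] = np.log(gclip[i, j] / gclip[i, i])
                    k += 1
        return cls(n_states=s, beta=beta)

    def matrix(self, z: Sequence[float] | None = None) -> np.ndarray:
        """Gamma evaluated at one covariate vector (S x S)."""
        zarr = np.zeros(len(self.covariates)) if z is None else np.asarray(z, dtype=float)
        return self.matrices(zarr[None, :])[0]

    def matrices(self, Z: np.ndarray) -> np.ndarray:
        """Gamma evaluated at each row of Z: returns (T, S, S)."""
        s, c = self.n_states, len(self.covariates)
        Z = np.asarray(Z, dtype=float)
        if c == 0:
            T = Z.shape[0] if Z.ndim >= 1 else 1
            Z = np.zeros((max(T, 1), 0))
        else:
            Z = Z.reshape(-1, c)
        zc = Z - self.centres
        # eta: (T, S*(S-1))
        eta = self.beta[:, 0][None, :] + zc @ self.beta[:, 1:].T
        T = Z.shape[0]
        # logits per row with an implicit 0 for the diagonal reference entry
        logits = np.zeros((T, s, s))
        k = 0
        for i in range(s):
            for j in range(s):
                if j != i:
                    logits[:, i, j] = eta[:, k]
                    k += 1
        logits -= logits.max(axis=2, keepdims=True)  # softmax stability
        out = np.exp(logits)
        out /= out.sum(axis=2, keepdims=True)
        return out


def transition_matrix(t: TransitionStructure, z=None) -> np.ndarray:
    """Evaluate Gamma at covariate values ``z`` (module-level convenience)."""
    return t.matrix(z)


@dataclass
class HmmModel:
    """N-state hidden Markov behaviour model."""

    n_states: int
    emissions: list[EmissionParams]
    transitions: TransitionStructure
    pi0: np.ndarray
    step_family: str = "truncnorm"

    def __post_init__(self):
        self.pi0 = np.asarray(self.pi0, dtype=float)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if len(self.emissions) != self.n_states:
            raise ValueError("one EmissionParams per state required")
        if self.transitions.n_states != self.n_states:
            raise ValueError("transition structure has wrong state count")
        if self.pi0.shape != (self.n_states,) or not np.isclose(self.pi0.sum(), 1.0):
            raise ValueError("pi0 must be a probability vector of length n_states")
        if np.any(self.pi0 < 0):
            raise ValueError("pi0 entries must be non-negative")

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.transitions.covariates

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "step_family": self.step_family,
            "emissions": [dataclasses.asdict(e) for e in self.emissions],
            "transitions": {
                "beta": self.transitions.beta.tolist(),
                "covariates": list(self.transitions.covariates),
                "centres": self.transitions.centres.tolist(),
            },
            "pi0": self.pi0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        tr = d["transitions"]
        return cls(
            n_states=d["n_states"],
            emissions=[EmissionParams(**e) for e in d["emissions"]],
            transitions=TransitionStructure(
                n_states=d["n_states"],
                beta=np.asarray(tr["beta"], dtype=float),
                covariates=tuple(tr.get("covariates", ())),
                centres=np.asarray(tr.get("centres", []), dtype=float),
            ),
            pi0=np.asarray(d["pi0"], dtype=float),
            step_family=d.get("step_family", "truncnorm"),
        )

    def save(self, path, provenance: dict | None = None) -> None:
        doc = self.to_dict()
        if provenance:
            doc["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "HmmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    """A fitted model with its achieved log likelihood and optimizer state."""

    model: HmmModel
    loglik: float
    n_iter: int
    converged: bool
    restart_id: int = 0
    canonical: bool = False

    def __post_init__(self):
        if self.converged and not np.isfinite(self.loglik):
            raise ValueError("a converged fit must have finite log likelihood")


def canonicalize(model: HmmModel) -> tuple[HmmModel, np.ndarray]:
    """Relabel states by ascending mean step length.

    Ties in mu break by sigma, then by original index, so the order is total
    and stable.  The permutation is applied consistently to pi0, the
    emission list and the transition beta table; the likelihood is invariant.
    Returns (relabelled model, permutation) with perm[new] = old.
    """
    keys = [(e.mu, e.sigma, i) for i, e in enumerate(model.emissions)]
    perm = np.array([i for _, _, i in sorted(keys)])
    s = model.n_states
    inv = np.empty(s, dtype=int)
    inv[perm] = np.arange(s)

    def _old_beta_index(i, j):
        return i * (s - 1) + (j if j < i else j - 1)

    new_beta = np.empty_like(model.transitions.beta)
    k = 0
    for i_new in range(s):
        for j_new in range(s):
            if j_new != i_new:
                new_beta[k] = model.transitions.beta[
                    _old_beta_index(perm[i_new], perm[j_new])
                ]
                k += 1
    return (
        HmmModel(
            n_states=s,
            emissions=[model.emissions[p] for p in perm],
            transitions=TransitionStructure(
                n_states=s,
                beta=new_beta,
                covariates=model.transitions.covariates,
                centres=model.transitions.centres.copy(),
            ),
            pi0=model.pi0[perm],
            step_family=model.step_family,
        ),
        perm,
    )


STATE_NAMES_3 = ("resting", "foraging", "travelling")

# Diagonal-dominant transition matrix used as the synthetic ground truth in
# recovery studies: resting highly persistent; leaving rest goes to foraging
# far more often than to travelling; leaving travel reaches foraging five
# times more often than rest; leaving foraging splits evenly.
DEFAULT_REFERENCE_GAMMA = np.array(
    [
        [0.90, 0.08, 0.02],
        [0.125, 0.75, 0.125],
        [0.042, 0.208, 0.75],
    ]
)


def reference_model(gamma: np.ndarray | None = None) -> HmmModel:
    """The shipped 3-state reference behaviour model for Sahel cattle.

    Emission parameters and the initial distribution come from the packaged
    fixture; the numeric transition matrix of the fitted field model was
    never published, so Gamma defaults to ``DEFAULT_REFERENCE_GAMMA`` (a
    stated convention) unless the caller supplies one.
    """
    with resources.files("herdhmm.data").joinpath("reference_model.json").open() as fh:
        doc = json.load(fh)
    g = DEFAULT_REFERENCE_GAMMA if gamma is None else np.asarray(gamma, dtype=float)
    return HmmModel(
        n_states=doc["n_states"],
        emissions=[EmissionParams(**e) for e in doc["emissions"]],
        transitions=TransitionStructure.from_matrix(g),
        pi0=np.asarray(doc["pi0"], dtype=float),
        step_family=doc.get("step_family", "truncnorm"),
    )
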