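"""Latent-variable (multidimensional IRT) representation of the Ising model.

With ``E Eᵀ`` the (shifted) connectivity, the Gaussian identity linearises
the quadratic form and yields the equivalent two-level model

    σ | θ  ~  Π_i exp(σ_i(e_i·θ + b_i)) / (2 cosh(e_i·θ + b_i)),
    f(θ)   ∝  exp(−‖θ‖²/2) Π_i 2 cosh(e_i·θ + b_i),

with one latent variable per retained eigen-component: nodes are independent
conditionally on θ, and integrating θ out returns the exact Ising
distribution (the partition function reappears only as the normalising
constant of f(θ)).  The conditional model is a multidimensional item-response
model with loadings ``e_i`` (rows of E) and intercepts ``b_i``; with equal
loadings at rank 1 it is the Rasch model, the Curie-Weiss special case.

Quadrature routines here are deliberately small-scale oracles (r ≤ 2,
n ≤ 20) used to certify that equivalence; the sampler, not quadrature,
handles general rank.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .ising_core import all_states, state_index
from .lowrank import LowRankLoadings


def log2cosh(x: np.ndarray) -> np.ndarray:
    """``log(2 cosh(x))`` stable for large ``|x|``."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax))


def _as_E(loadings) -> np.ndarray:
    if isinstance(loadings, LowRankLoadings):
        return loadings.E
    return np.atleast_2d(np.asarray(loadings, dtype=float))


def log_irt_prob(loadings, b, theta, sigma) -> float:
    """Log of the conditional (IRT) probability ``p(σ | θ)``."""
    E = _as_E(loadings)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if E.shape[0] != b.shape[0] or E.shape[0] != sigma.shape[0]:
        raise ValueError(
            f"dimension mismatch: E is {E.shape}, b has length {b.shape[0]}, "
            f"state has length {sigma.shape[0]}"
        )
    if E.shape[1] != theta.shape[0]:
        raise ValueError(
            f"dimension mismatch: E has rank {E.shape[1]} but theta has length {theta.shape[0]}"
        )
    x = E @ theta + b
    return float(np.sum(sigma * x - log2cosh(x)))


def irt_prob(loadings, b, theta, sigma) -> float:
    """Conditional probability of a full state given the latent variables.

    Nodes are conditionally independent; each factor is
    ``exp(σ_i(e_i·θ + b_i)) / (2 cosh(e_i·θ + b_i))``.
    """
    return float(np.exp(log_irt_prob(loadings, b, theta, sigma)))


def latent_logdensity_unnorm(loadings, b, theta) -> np.ndarray | float:
    """Unnormalised log density of the latent variables,
    ``−‖θ‖²/2 + Σ_i log 2cosh(e_i·θ + b_i)``.

    ``theta`` may be a single vector of length r or an ``(m, r)`` stack of
    evaluation points (a grid); the additive constant ``−log Z + const`` is
    omitted.
    """
    E = _as_E(loadings)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim <= 1
    th = np.atleast_2d(theta if theta.ndim else theta[None])
    if th.shape[1] != E.shape[1]:
        raise ValueError(
            f"dimension mismatch: E has rank {E.shape[1]} but theta has {th.shape[1]} columns"
        )
    x = th @ E.T + b
    val = -0.5 * np.sum(th**2, axis=1) + np.sum(log2cosh(x), axis=1)
    return float(val[0]) if single else val


def _gh_grid(r: int, n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor Gauss-Hermite grid for ∫ e^{−‖θ‖²/2} g(θ) dθ (r ≤ 2)."""
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    theta1 = np.sqrt(2.0) * x
    logw1 = np.log(w) + 0.5 * np.log(2.0)
    if r == 1:
        return theta1[:, None], logw1
    tg = np.stack(np.meshgrid(theta1, theta1, indexing="ij"), axis=-1).reshape(-1, 2)
    lw = (logw1[:, None] + logw1[None, :]).ravel()
    return tg, lw


def marginal_distribution_quadrature(loadings, b, n_quad: int = 64) -> np.ndarray:
    """Quadrature marginal ``∫ p(σ|θ) f(θ) dθ`` for every state.

    Returns probabilities over all ``2^n`` states in enumeration order,
    normalised across states.  Oracle-only: refuses rank > 2.
    """
    E = _as_E(loadings)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    n, r = E.shape
    if r > 2:
        raise ValueError("quadrature marginal is an oracle for r <= 2 only")
    if n > 20:
        raise ValueError("quadrature marginal enumerates states; n <= 20 required")
    states = all_states(n).astype(float)
    theta, logw = _gh_grid(r, n_quad)
    # log kernel of state s at node theta_g: b·σ_s + σ_s·(E θ_g)
    proj = states @ (E @ theta.T)  # (2^n, G)
    logm = states @ b + logsumexp(proj + logw[None, :], axis=1)
    logm -= logsumexp(logm)
    return np.exp(logm)


def marginal_prob_quadrature(loadings, b, sigma, n_quad: int = 64) -> float:
    """Quadrature marginal probability of one state (see distribution form)."""
    p = marginal_distribution_quadrature(loadings, b, n_quad=n_quad)
    return float(p[state_index(sigma)])


@dataclasses.dataclass(frozen=True)
class ThetaPosterior:
    """Normal full-conditional of θ for one replication: N(Eᵀσ, I_r)."""

    mean: np.ndarray
    covariance: np.ndarray


def theta_posterior(loadings, sigma) -> ThetaPosterior:
    """Full conditional of the latent vector given one state.

    A multivariate normal with mean ``Eᵀσ`` and identity covariance; the
    main effects cancel from the θ-conditional.
    """
    E = _as_E(loadings)
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.shape[0] != E.shape[0]:
        raise ValueError(
            f"dimension mismatch: state has length {sigma.shape[0]} but E has {E.shape[0]} rows"
        )
    return ThetaPosterior(mean=E.T @ sigma, covariance=np.eye(E.shape[1]))


# ---------------------------------------------------------------------------
# Curie-Weiss special case
# ---------------------------------------------------------------------------


def curie_weiss_logdensity(a: float, n: int, theta) -> np.ndarray | float:
    """Latent log density of the Curie-Weiss model (rank 1, b = 0).

    Mean-field scaling: every pair interacts with strength ``a/n``, so the
    loading is ``e_i = √(a/n)`` for every node and the unnormalised log
    density is ``−θ²/2 + n log 2cosh(√(a/n) θ)``.  Its curvature at the
    origin is ``a − 1`` for every n, so the density turns bimodal at a = 1.
    """
    if a < 0:
        raise ValueError("coupling a must be non-negative")
    if n < 2:
        raise ValueError("Curie-Weiss model needs n >= 2 nodes")
    theta = np.asarray(theta, dtype=float)
    return -0.5 * theta**2 + n * log2cosh(np.sqrt(a / n) * theta)


def curie_weiss_curvature(a: float, n: int, h: float = 1e-4) -> float:
    """Second derivative of the Curie-Weiss log density at θ = 0 (central
    difference; analytically equal to a − 1)."""
    f = lambda t: curie_weiss_logdensity(a, n, t)
    return float((f(h) - 2.0 * f(0.0) + f(-h)) / h**2)


def bimodality_threshold(n: int = 10, lo: float = 0.05, hi: float = 4.0) -> float:
    """Coupling at which the Curie-Weiss latent density turns bimodal,
    located as the sign change of the origin curvature."""
    return float(brentq(lambda a: curie_weiss_curvature(a, n), lo, hi, xtol=1e-10))


def count_modes(values, merge_tol: float = 1e-12, min_points: int = 2001) -> int:
    """Number of strict interior local maxima of a function tabulated on a
    uniform grid.

    Plateaus (consecutive values within ``merge_tol``) are merged into a
    single point before comparison; boundary grid points never count as
    modes.  The grid must be fine (≥ ``min_points``) and span the support
    comfortably, otherwise modes may be missed.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] < min_points:
        raise ValueError(f"grid too coarse: need at least {min_points} points")
    # merge plateaus
    keep = np.concatenate([[True], np.abs(np.diff(v)) > merge_tol])
    c = v[keep]
    if c.shape[0] < 3:
        return 0
    interior = (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
    return int(np.count_nonzero(interior))
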