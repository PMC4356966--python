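"""Posterior predictive checks on the sufficient statistic S.

Replicate datasets from posterior draws of (E, b) through the latent
representation, average their sufficient statistics into ``S_rep``, and
compare with the observed ``S = Σ_p σ_p σ_pᵀ`` via the residual matrix and
the correlation of strictly-lower-triangle entries.  Raising the rank of the
approximation should predict more of the structure of S, with the rank-one
component typically already capturing most of the variation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .ising_core import Dataset, sufficient_statistic
from .latent import _as_E
from .sampler import Chains, draw_theta


@dataclasses.dataclass
class PPCResult:
    """Observed S, expected replicated S_rep, residual and lower-triangle
    correlation for one rank."""

    S: np.ndarray
    S_rep: np.ndarray
    residual: np.ndarray
    lower_tri_correlation: float
    rank: int


def lower_triangle(M: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries as a flat vector (diagonal excluded)."""
    i, j = np.tril_indices(M.shape[0], k=-1)
    return np.asarray(M)[i, j]


def replicate_dataset(
    E_draw, b_draw, theta_draw: np.ndarray, rng: np.random.Generator
) -> Dataset:
    """One replicated dataset: nodes independent given θ, with
    ``P(σ_pi = +1) = logistic(2(e_i·θ_p + b_i))``."""
    E = _as_E(E_draw)
    b = np.atleast_1d(np.asarray(b_draw, dtype=float))
    theta = np.atleast_2d(np.asarray(theta_draw, dtype=float))
    if theta.shape[1] != E.shape[1] or b.shape[0] != E.shape[0]:
        raise ValueError(
            f"dimension mismatch: E is {E.shape}, b has length {b.shape[0]}, "
            f"theta is {theta.shape}"
        )
    p = expit(2.0 * (theta @ E.T + b))
    states = np.where(rng.uniform(size=p.shape) < p, 1, -1).astype(np.int8)
    return Dataset(states)


def ppc_check(
    data: Dataset,
    chains: Chains,
    n_rep: int = 100,
    seed=None,
    redraw_theta: bool = True,
) -> PPCResult:
    """Posterior predictive check of the sufficient statistic.

    ``n_rep`` equally spaced post-burn-in draws are selected; for each, a
    fresh latent matrix is drawn at that draw's parameters (default) or the
    stored one reused, a dataset is replicated, and the sufficient
    statistics are averaged into ``S_rep``.  The correlation is computed
    over the n(n−1)/2 strictly-lower-triangle pairs (the diagonal is the
    constant N).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")
    if chains.n_draws < 1:
        raise ValueError("chains contain no draws")
    if not redraw_theta and chains.theta is None:
        raise ValueError("chains were run without store_theta; cannot reuse theta")
    rng = np.random.default_rng(seed)
    picks = np.unique(
        np.linspace(0, chains.n_draws - 1, num=min(n_rep, chains.n_draws)).astype(int)
    )
    S = sufficient_statistic(data).astype(float)
    S_rep = np.zeros_like(S)
    for k in picks:
        E_k, b_k = chains.E[k], chains.b[k]
        if redraw_theta:
            theta = draw_theta(E_k, data, rng)
        else:
            theta = chains.theta[k]
        rep = replicate_dataset(E_k, b_k, theta, rng)
        S_rep += sufficient_statistic(rep)
    S_rep /= picks.shape[0]
    residual = S - S_rep
    corr = float(np.corrcoef(lower_triangle(S), lower_triangle(S_rep))[0, 1])
    return PPCResult(
        S=S, S_rep=S_rep, residual=residual, lower_tri_correlation=corr, rank=chains.rank
    )


def save_scatter(result: PPCResult, path) -> None:
    """Tidy two-column export (S_lower, S_rep_lower) for scatter plots
    against the first bisection."""
    pd.DataFrame(
        {
            "S_lower": lower_triangle(result.S),
            "S_rep_lower": lower_triangle(result.S_rep),
        }
    ).to_csv(path, index=False)
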