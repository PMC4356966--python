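"""Synthetic network generators and the exact data-augmented sampler.

Two network flavours are emulated.  Nearest-neighbour lattices (the
physics flavour) have a near-linear eigenvalue spectrum and are *not* well
approximated at low rank.  Dense low-rank networks (the social-science
flavour) have a dominant all-positive first component — every node
positively tied to every other — plus a few zero-sum "contrast" components
that strengthen interactions within blocks of nodes and weaken them across
blocks; their spectra drop sharply after the first r eigenvalues.  The
Curie-Weiss model (all pairwise interactions equal to a/n) is the rank-1
degenerate case.

``generate_augmented`` samples exactly from an Ising model of any size by
Gibbs alternation on the joint (σ, θ) of the latent representation — both
conditionals are closed-form, so no partition function is needed.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.special import expit

from .ising_core import Dataset, IsingModel
from .latent import _as_E


def make_lattice(side: int, coupling: float, wrap: bool = False) -> IsingModel:
    """Square-lattice nearest-neighbour network (n = side², b = 0).

    ``wrap=True`` gives the torus (every node degree 4); otherwise edges
    stop at the boundary.
    """
    if side < 2:
        raise ValueError("lattice side must be at least 2")
    g = nx.grid_2d_graph(side, side, periodic=wrap)
    nodes = sorted(g.nodes())
    A = coupling * nx.to_numpy_array(g, nodelist=nodes)
    return IsingModel(b=np.zeros(side * side), A=A)


def make_curie_weiss(n: int, a: float) -> IsingModel:
    """Fully connected network with all pairwise interactions equal to a/n
    (mean-field scaling), zero main effects."""
    if n < 2:
        raise ValueError("need n >= 2 nodes")
    if a < 0:
        raise ValueError("coupling a must be non-negative")
    A = np.full((n, n), a / n)
    np.fill_diagonal(A, 0.0)
    return IsingModel(b=np.zeros(n), A=A)


def make_dense_lowrank(
    n: int,
    r: int,
    general_band: tuple[float, float] = (0.08, 0.38),
    contrast_scale: float = 0.12,
    b_scale: float = 0.2,
    noise: float = 0.0,
    seed=None,
) -> tuple[IsingModel, np.ndarray]:
    """Dense rank-r network with a general factor plus block contrasts.

    Column 1 of the true loading matrix E is all-positive (entries uniform
    in ``general_band``); columns 2..r are zero-sum contrasts over k
    contiguous blocks with alternating signs and jittered magnitudes around
    ``contrast_scale``.  The connectivity is ``E Eᵀ`` with zero diagonal
    (plus optional symmetric dense noise); main effects are small, uniform
    in ±``b_scale``.  Returns the model together with the true E for
    recovery tests.
    """
    if not 1 <= r <= n:
        raise ValueError(f"need n >= r >= 1, got n={n}, r={r}")
    lo, hi = general_band
    if not 0 < lo < hi:
        raise ValueError("general_band must be a positive increasing pair")
    if contrast_scale < 0 or noise < 0:
        raise ValueError("scales must be non-negative")
    rng = np.random.default_rng(seed)
    E = np.zeros((n, r))
    E[:, 0] = rng.uniform(lo, hi, size=n)
    for k in range(1, r):
        blocks = np.minimum((np.arange(n) * (k + 1)) // n, k)
        signs = np.where(blocks % 2 == 0, 1.0, -1.0)
        col = signs * contrast_scale * rng.uniform(0.6, 1.4, size=n)
        E[:, k] = col - col.mean()  # zero-sum contrast
    A = E @ E.T
    if noise > 0:
        G = rng.normal(scale=noise, size=(n, n))
        A = A + (G + G.T) / 2.0
    np.fill_diagonal(A, 0.0)
    b = rng.uniform(-b_scale, b_scale, size=n)
    return IsingModel(b=b, A=A), E


def generate_augmented(
    loadings,
    b,
    N: int,
    burn_in: int = 100,
    seed=None,
    mode: str = "independent",
    thin: int = 5,
) -> Dataset:
    """Sample N network states via exact Gibbs on the joint (σ, θ).

    Alternates ``θ | σ ~ N(Eᵀσ, I_r)`` with independent node flips
    ``P(σ_i = +1 | θ) = logistic(2(e_i·θ + b_i))``; the stationary law of σ
    is the Ising model with connectivity ``E Eᵀ`` (off-diagonal) and main
    effects b.  Default runs one independent chain per replication
    (exchangeable rows at the cost of ``burn_in`` sweeps each, vectorised
    across rows); ``mode="long"`` thins a single long chain instead.
    """
    E = _as_E(loadings)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    n, r = E.shape
    if b.shape[0] != n:
        raise ValueError(f"dimension mismatch: E has {n} rows, b has length {b.shape[0]}")
    if N < 1:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)

    def sweep(states: np.ndarray) -> np.ndarray:
        theta = states.astype(float) @ E + rng.standard_normal((states.shape[0], r))
        p = expit(2.0 * (theta @ E.T + b))
        return np.where(rng.uniform(size=p.shape) < p, 1, -1).astype(np.int8)

    if mode == "independent":
        states = np.where(rng.uniform(size=(N, n)) < 0.5, 1, -1).astype(np.int8)
        for _ in range(max(1, burn_in)):
            states = sweep(states)
        return Dataset(states)
    if mode == "long":
        state = np.where(rng.uniform(size=(1, n)) < 0.5, 1, -1).astype(np.int8)
        for _ in range(max(1, burn_in)):
            state = sweep(state)
        out = np.empty((N, n), dtype=np.int8)
        for p_idx in range(N):
            for _ in range(max(1, thin)):
                state = sweep(state)
            out[p_idx] = state[0]
        return Dataset(out)
    raise ValueError(f"unknown mode {mode!r}")
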