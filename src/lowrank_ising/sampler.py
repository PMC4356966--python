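"""Full-data-information estimation of low-rank Ising networks.

The Gibbs scheme alternates

1. exact normal draws of the latent variables, ``θ_p | σ_p ~ N(Eᵀσ_p, I_r)``
   for each replication ``p``, with
2. scalar independence Metropolis-Hastings updates of every main effect
   ``b_i`` and every loading ``e_ir`` from their *partial* conditional
   distributions — likelihood × prior with the latent-variable marginal
   (and hence the partition function) left out.

For a scalar parameter ``w`` the partial conditional takes the form

    π(w) ∝ f(w) · Π_p F_p(w)^{y_p} (1 − F_p(w))^{1 − y_p},

a prior density times a product of Bernoulli terms whose success
probabilities are *monotone logistic CDFs evaluated at w* (locations and
scales determined by the current θ and the other parameters; responses
``y_p = (σ_p + 1)/2``).  The order-statistic proposal exploits this: draw
one value from the prior and one from each F_p, and propose the draw whose
rank among the N+1 values is the total score ``y_+ + 1``.  Conditional on
the realised below/above pattern, the proposal density has exactly the form
of the target with the prior and one observation swapped, so the
Metropolis-Hastings correction is cheap and the acceptance rate grows with
N.  The partition function is never evaluated anywhere in this module.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal

import numpy as np
from scipy.special import log_expit, log_ndtr

from .ising_core import Dataset, sufficient_statistic
from .latent import _as_E
from .lowrank import loadings_from_connectivity

logger = logging.getLogger("lowrank_ising")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Prior:
    """Proper symmetric prior for one scalar parameter.

    The default logistic family keeps the prior in the same family as the
    observation CDFs, so the prior draw is the natural "switched-places"
    element of the order-statistic proposal; a normal family is available.
    """

    family: Literal["logistic", "normal"] = "logistic"
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")

    def logpdf(self, w: float) -> float:
        z = (w - self.loc) / self.scale
        if self.family == "logistic":
            return float(log_expit(z) + log_expit(-z) - math.log(self.scale))
        return float(-0.5 * z * z - _LOG_SQRT_2PI - math.log(self.scale))

    def logcdf(self, w: float) -> float:
        z = (w - self.loc) / self.scale
        return float(log_expit(z) if self.family == "logistic" else log_ndtr(z))

    def logsf(self, w: float) -> float:
        z = (w - self.loc) / self.scale
        return float(log_expit(-z) if self.family == "logistic" else log_ndtr(-z))

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "logistic":
            return float(rng.logistic(self.loc, self.scale))
        return float(rng.normal(self.loc, self.scale))


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Independent priors for main effects and loading entries."""

    b: Prior = Prior()
    e: Prior = Prior()


# ---------------------------------------------------------------------------
# observation CDF families (the F_p of the partial conditional)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LogisticFamily:
    """N monotone logistic CDFs ``F_p`` plus 0/1 responses ``y_p``.

    ``F_p(w) = logistic((w − loc_p)/scale_p)`` with every scale positive, so
    every member is increasing in the parameter ``w``.
    """

    loc: np.ndarray
    scale: np.ndarray
    y: np.ndarray  # boolean responses

    @property
    def n_obs(self) -> int:
        return self.loc.shape[0]

    def _z(self, w: float) -> np.ndarray:
        return (w - self.loc) / self.scale

    def log_cdf(self, w: float) -> np.ndarray:
        return log_expit(self._z(w))

    def log_sf(self, w: float) -> np.ndarray:
        return log_expit(-self._z(w))

    def log_pdf_one(self, w: float, p: int) -> float:
        z = (w - self.loc[p]) / self.scale[p]
        return float(log_expit(z) + log_expit(-z) - np.log(self.scale[p]))

    def log_bernoulli(self, w: float, resp: np.ndarray) -> np.ndarray:
        """Elementwise ``resp·log F + (1−resp)·log(1−F)`` at w."""
        z = self._z(w)
        return log_expit(np.where(resp, z, -z))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.logistic(self.loc, self.scale)


def obs_cdf_family(
    kind: Literal["b", "e"],
    i: int,
    comp: int,
    theta: np.ndarray,
    E: np.ndarray,
    b: np.ndarray,
    data: Dataset,
) -> LogisticFamily:
    """Partial-conditional CDF family for one scalar parameter.

    For ``w = b_i``: location ``−θ_p·e_i``, scale ½, response from ``σ_pi``.
    For ``w = e_ir``: location ``−(b_i + rest_p)/θ_pr`` and scale
    ``1/(2|θ_pr|)`` where ``rest_p = Σ_{s≠r} θ_ps e_is``; when ``θ_pr < 0``
    the response is flipped so that every CDF is increasing in w.
    Replications with ``θ_pr = 0`` contribute a constant factor and are
    dropped.
    """
    y = data.states[:, i] > 0
    if kind == "b":
        loc = -(theta @ E[i])
        scale = np.full(loc.shape, 0.5)
        return LogisticFamily(loc=loc, scale=scale, y=y)
    if kind != "e":
        raise ValueError(f"unknown parameter kind {kind!r}")
    t = theta[:, comp]
    keep = t != 0.0
    t = t[keep]
    rest = b[i] + theta[keep] @ E[i] - t * E[i, comp]
    loc = -rest / t
    scale = 1.0 / (2.0 * np.abs(t))
    y_eff = np.where(t < 0, ~y[keep], y[keep])
    return LogisticFamily(loc=loc, scale=scale, y=y_eff)


# ---------------------------------------------------------------------------
# order-statistic proposal and Metropolis-Hastings step
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OSProposal:
    """A realised order-statistic proposal.

    ``source`` is 0 when the proposed value is the prior draw, else the
    (1-based) index of the observation whose draw was selected.  ``below``
    records the realised indicator pattern ``z < w_star`` over all N+1
    draws (prior first); the entry at ``source`` is meaningless.
    """

    w_star: float
    source: int
    below: np.ndarray


def os_propose(
    prior: Prior, family: LogisticFamily, y_plus: int, rng: np.random.Generator
) -> OSProposal:
    """Draw ``z_0 ~ prior`` and ``z_p ~ F_p`` and propose the value whose
    rank among the N+1 draws is ``y_+ + 1``.

    Equivalently: the unique column j of the pairwise indicator matrix
    ``x_pj = (z_p < z_j)`` with column total ``y_+`` (ranks of distinct reals
    are a permutation, so exactly one column qualifies).
    """
    N = family.n_obs
    if not 0 <= y_plus <= N:
        raise ValueError(f"total score {y_plus} outside 0..{N}")
    z = np.empty(N + 1)
    z[0] = prior.sample(rng)
    z[1:] = family.sample(rng)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite draw in order-statistic proposal")
    j = int(np.argsort(z, kind="stable")[y_plus])
    w_star = float(z[j])
    return OSProposal(w_star=w_star, source=j, below=z < w_star)


def _log_target(w: float, prior: Prior, family: LogisticFamily) -> float:
    return prior.logpdf(w) + float(family.log_bernoulli(w, family.y).sum())


def _log_proposal(w: float, prior: Prior, family: LogisticFamily, prop: OSProposal) -> float:
    """Density of the selected draw conditional on the realised pattern:
    source pdf times the Bernoulli factors of every other draw."""
    j = prop.source
    obs_terms = family.log_bernoulli(w, prop.below[1:])
    if j == 0:
        return prior.logpdf(w) + float(obs_terms.sum())
    total = float(obs_terms.sum() - obs_terms[j - 1])
    prior_term = prior.logcdf(w) if prop.below[0] else prior.logsf(w)
    return family.log_pdf_one(w, j - 1) + prior_term + total


def mh_step(
    w_current: float,
    prior: Prior,
    family: LogisticFamily,
    proposal: OSProposal,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Independence MH accept/reject of the order-statistic proposal.

    Accepts with min{1, [π̃(w*) q̃(w)] / [π̃(w) q̃(w*)]} where q̃ is the
    proposal density evaluated with the realised indicator pattern;
    unnormalised densities suffice.  A non-finite log ratio rejects with a
    warning.
    """
    w_star = proposal.w_star
    log_ratio = (
        _log_target(w_star, prior, family)
        - _log_proposal(w_star, prior, family, proposal)
        - _log_target(w_current, prior, family)
        + _log_proposal(w_current, prior, family, proposal)
    )
    if not np.isfinite(log_ratio):
        logger.warning("non-finite MH log ratio at w*=%.4g; proposal rejected", w_star)
        return w_current, False
    if np.log(rng.uniform()) < log_ratio:
        return w_star, True
    return w_current, False


def update_parameter(
    w_current: float, prior: Prior, family: LogisticFamily, rng: np.random.Generator
) -> tuple[float, bool]:
    """One full order-statistic MH update of a scalar parameter."""
    y_plus = int(np.count_nonzero(family.y))
    prop = os_propose(prior, family, y_plus, rng)
    return mh_step(w_current, prior, family, prop, rng)


def log_partial_conditional(w, prior: Prior, family: LogisticFamily) -> np.ndarray:
    """Unnormalised log partial conditional on a grid of w values (oracle
    helper for certifying the MH chain against a grid-normalised density)."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    return np.array([_log_target(wi, prior, family) for wi in w])


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ChainConfig:
    """Length, burn-in, master seed and θ-storage of one Gibbs run."""

    iterations: int = 1000
    burn_in: int = 250
    seed: int = 0
    store_theta: bool = False

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")


@dataclasses.dataclass
class Chains:
    """Post-burn-in draws of (E, b) with per-parameter acceptance rates."""

    b: np.ndarray  # (m, n)
    E: np.ndarray  # (m, n, r)
    accept_b: np.ndarray  # (n,)
    accept_E: np.ndarray  # (n, r)
    config: ChainConfig
    prior: PriorSpec
    theta: np.ndarray | None = None  # (m, N, r) when stored

    @property
    def n_draws(self) -> int:
        return self.b.shape[0]

    @property
    def n(self) -> int:
        return self.b.shape[1]

    @property
    def rank(self) -> int:
        return self.E.shape[2]

    def reconstruction_draws(self, zero_diagonal: bool = True) -> np.ndarray:
        """Per-draw connectivity reconstructions ``E Eᵀ`` (rotation-invariant)."""
        A = np.einsum("mik,mjk->mij", self.E, self.E)
        if zero_diagonal:
            idx = np.arange(self.n)
            A[:, idx, idx] = 0.0
        return A

    def posterior_mean_connectivity(self, zero_diagonal: bool = True) -> np.ndarray:
        return self.reconstruction_draws(zero_diagonal).mean(axis=0)

    def principal_loadings(self):
        """Loadings of the eigendecomposed posterior-mean reconstruction —
        a deterministic rotation for reporting (raw chains stay unrotated)."""
        from .lowrank import spectrum, truncate

        mean_A = self.reconstruction_draws(zero_diagonal=False).mean(axis=0)
        return truncate(spectrum(mean_A), self.rank)


def draw_theta(loadings, data: Dataset, rng: np.random.Generator) -> np.ndarray:
    """Exact draw of the N×r latent matrix: ``θ_p ~ N(Eᵀσ_p, I_r)``."""
    E = _as_E(loadings)
    if E.shape[0] != data.n:
        raise ValueError(
            f"dimension mismatch: E has {E.shape[0]} rows but data has {data.n} nodes"
        )
    mean = data.states.astype(float) @ E
    return mean + rng.standard_normal(mean.shape)


def _spectral_init(data: Dataset, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Warm start: loadings from the (zero-diagonal) scaled sufficient
    statistic, intercepts from arctanh of the node means."""
    S = sufficient_statistic(data).astype(float) / data.N
    loadings = loadings_from_connectivity(S, rank)
    m = np.clip(data.states.mean(axis=0), -0.95, 0.95)
    return loadings.E.copy(), np.arctanh(m)


def run(
    data: Dataset,
    rank: int,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    init: str = "spectral",
) -> Chains:
    """Run the full-data-information Gibbs sampler.

    Each iteration draws the latent matrix exactly and then performs one
    scalar order-statistic MH update per parameter, sweeping b first and
    then E row-major.  The partition function is never computed.  Divergence
    (a non-finite parameter) aborts with the iteration index.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    n = data.n
    if not 1 <= rank <= n:
        raise ValueError(f"rank must satisfy 1 <= rank <= n={n}")
    rng = np.random.default_rng(config.seed)

    if init == "spectral":
        E, b = _spectral_init(data, rank)
    elif init == "random":
        E = 0.1 * rng.standard_normal((n, rank))
        b = np.zeros(n)
    else:
        raise ValueError(f"unknown init {init!r}")

    m = config.iterations - config.burn_in
    out_b = np.empty((m, n))
    out_E = np.empty((m, n, rank))
    out_theta = np.empty((m, data.N, rank)) if config.store_theta else None
    acc_b = np.zeros(n)
    acc_E = np.zeros((n, rank))

    for it in range(config.iterations):
        theta = draw_theta(E, data, rng)
        recording = it >= config.burn_in
        for i in range(n):
            fam = obs_cdf_family("b", i, 0, theta, E, b, data)
            b[i], accepted = update_parameter(b[i], prior.b, fam, rng)
            if recording and accepted:
                acc_b[i] += 1
        for i in range(n):
            for s in range(rank):
                fam = obs_cdf_family("e", i, s, theta, E, b, data)
                E[i, s], accepted = update_parameter(E[i, s], prior.e, fam, rng)
                if recording and accepted:
                    acc_E[i, s] += 1
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(E))):
            raise RuntimeError(f"sampler diverged: non-finite parameter at iteration {it}")
        if recording:
            k = it - config.burn_in
            out_b[k] = b
            out_E[k] = E
            if out_theta is not None:
                out_theta[k] = theta

    return Chains(
        b=out_b,
        E=out_E,
        accept_b=acc_b / m,
        accept_E=acc_E / m,
        config=config,
        prior=prior,
        theta=out_theta,
    )


# ---------------------------------------------------------------------------
# chain I/O: delimited text + JSON sidecar
# ---------------------------------------------------------------------------


def chains_to_frame(chains: Chains):
    """One row per stored iteration, columns labelled b[i] and E[i,r]."""
    import pandas as pd

    n, r = chains.n, chains.rank
    cols = {f"b[{i}]": chains.b[:, i] for i in range(n)}
    for i in range(n):
        for s in range(r):
            cols[f"E[{i},{s}]"] = chains.E[:, i, s]
    return pd.DataFrame(cols)


def write_chains(chains: Chains, csv_path, json_path) -> None:
    """Write draws as CSV and config/priors/acceptance rates as JSON."""
    import json

    chains_to_frame(chains).to_csv(csv_path, index=False)
    meta = {
        "n": chains.n,
        "rank": chains.rank,
        "iterations": chains.config.iterations,
        "burn_in": chains.config.burn_in,
        "seed": chains.config.seed,
        "prior": {
            "b": dataclasses.asdict(chains.prior.b),
            "e": dataclasses.asdict(chains.prior.e),
        },
        "accept_b": chains.accept_b.tolist(),
        "accept_E": chains.accept_E.tolist(),
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_chains(csv_path, json_path) -> Chains:
    """Reload a chain written by :func:`write_chains`."""
    import json

    import pandas as pd

    with open(json_path, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    n, r = meta["n"], meta["rank"]
    b = df[[f"b[{i}]" for i in range(n)]].to_numpy()
    E = np.empty((len(df), n, r))
    for i in range(n):
        for s in range(r):
            E[:, i, s] = df[f"E[{i},{s}]"].to_numpy()
    config = ChainConfig(
        iterations=meta["iterations"], burn_in=meta["burn_in"], seed=meta["seed"]
    )
    prior = PriorSpec(b=Prior(**meta["prior"]["b"]), e=Prior(**meta["prior"]["e"]))
    return Chains(
        b=b,
        E=E,
        accept_b=np.asarray(meta["accept_b"]),
        accept_E=np.asarray(meta["accept_E"]),
        config=config,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# Curie-Weiss specialisation (single parameter a)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CurieWeissChains:
    """Draws of the Curie-Weiss coupling a (and the tied loading e = √(a/n))."""

    a: np.ndarray
    e: np.ndarray
    accept_rate: float
    config: ChainConfig


def curie_weiss_obs_family(theta: np.ndarray, data: Dataset) -> LogisticFamily:
    """CDF family of the tied loading e given the latent values.

    Every node of replication p contributes one Bernoulli term with CDF
    location 0 and scale ``1/(2|θ_p|)``, response flipped when ``θ_p < 0``.
    """
    theta = np.asarray(theta, dtype=float)
    keep = theta != 0.0
    t = theta[keep]
    n = data.n
    scale = np.repeat(1.0 / (2.0 * np.abs(t)), n)
    y = data.states[keep] > 0
    y_eff = np.where((t < 0)[:, None], ~y, y).ravel()
    return LogisticFamily(loc=np.zeros(scale.shape), scale=scale, y=y_eff)


def fit_curie_weiss(
    data: Dataset, prior: Prior | None = None, config: ChainConfig | None = None
) -> CurieWeissChains:
    """Single-parameter chain for the Curie-Weiss model.

    Parameterised through the tied loading ``e`` (so ``a = n e²``, main
    effects zero); alternates ``θ_p ~ N(e Σ_i σ_pi, 1)`` with one
    order-statistic MH update of e per iteration.
    """
    prior = prior or Prior()
    config = config or ChainConfig()
    rng = np.random.default_rng(config.seed)
    rowsum = data.states.sum(axis=1).astype(float)
    n = data.n
    e = 0.0
    m = config.iterations - config.burn_in
    out_e = np.empty(m)
    accepted_total = 0
    for it in range(config.iterations):
        theta = e * rowsum + rng.standard_normal(data.N)
        fam = curie_weiss_obs_family(theta, data)
        e, accepted = update_parameter(e, prior, fam, rng)
        if not np.isfinite(e):
            raise RuntimeError(f"sampler diverged: non-finite parameter at iteration {it}")
        if it >= config.burn_in:
            out_e[it - config.burn_in] = e
            accepted_total += accepted
    return CurieWeissChains(
        a=n * out_e**2, e=out_e, accept_rate=accepted_total / m, config=config
    )
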