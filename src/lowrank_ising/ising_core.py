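"""Exact computations for small Ising networks.

The Ising model over binary spins ``σ ∈ {−1, +1}^n`` is

    p(σ) = exp(b·σ + ½ σᵀ A σ) / Z,

with main effects ``b``, symmetric connectivity matrix ``A`` and partition
function ``Z`` summing the unnormalised weight over all ``2^n`` states.  The
diagonal of ``A`` contributes the constant ``½ trace(A)`` (since ``σ_i² = 1``)
and therefore carries no information: every probability is invariant under
``A → A + cI``.

Everything here is enumeration-based and guarded at ``n ≤ 20``; these routines
are the model definition and the brute-force oracle for the latent-variable
machinery, not the estimation path for large networks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

#: Largest node count for which exact enumeration (2^n states) is permitted.
ENUMERATION_LIMIT = 20

_SYMMETRY_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class IsingModel:
    """Main effects ``b`` and symmetric connectivity matrix ``A``.

    Parameters
    ----------
    b
        Real vector of length ``n`` (per-node external fields).
    A
        Real symmetric ``n × n`` matrix of pairwise interactions.  The
        diagonal is retained as given but is not identifiable.
    """

    b: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        A = np.asarray(self.A, dtype=float)
        if b.ndim != 1:
            raise ValueError(f"b must be a vector, got shape {b.shape}")
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        if A.shape[0] != b.shape[0]:
            raise ValueError(
                f"dimension mismatch: dim(b)={b.shape[0]} but A is {A.shape[0]}x{A.shape[1]}"
            )
        if not np.all(np.isfinite(b)) or not np.all(np.isfinite(A)):
            raise ValueError("model parameters must be finite")
        if np.max(np.abs(A - A.T), initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("A must be symmetric to within 1e-12")
        b.setflags(write=False)
        A.setflags(write=False)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "A", A)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.b.shape[0]


@dataclasses.dataclass
class Dataset:
    """``N × n`` matrix of ±1 network-state replications.

    Rows are independent realisations of the network state; columns are
    nodes.  On disk states are stored as 0/1 (``y = (σ + 1)/2``); in memory
    they are always ±1.
    """

    states: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        states = np.atleast_2d(np.asarray(self.states))
        if states.ndim != 2:
            raise ValueError(f"states must be a matrix, got shape {states.shape}")
        if states.shape[0] < 1:
            raise ValueError("dataset must contain at least one replication")
        if not np.all(np.abs(states) == 1):
            raise ValueError("dataset entries must all be -1 or +1")
        self.states = states.astype(np.int8)
        if self.labels is not None and len(self.labels) != states.shape[1]:
            raise ValueError("number of labels must match number of nodes")

    @property
    def N(self) -> int:
        """Number of replications (rows)."""
        return self.states.shape[0]

    @property
    def n(self) -> int:
        """Number of nodes (columns)."""
        return self.states.shape[1]


def _check_state(sigma: np.ndarray, n: int) -> np.ndarray:
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: state has length {sigma.shape[0]} but model has n={n}"
        )
    if not np.all(np.abs(sigma) == 1.0):
        raise ValueError("state entries must all be -1 or +1")
    return sigma


def _check_enumerable(n: int, what: str) -> None:
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"{what} requires enumerating 2^{n} states (guard: n <= "
            f"{ENUMERATION_LIMIT}); use the latent representation "
            "(latent / sampler / synth.generate_augmented) for larger networks"
        )


def all_states(n: int) -> np.ndarray:
    """All ``2^n`` spin states as a ``(2^n, n)`` ±1 matrix.

    Node 0 is the least-significant bit of the row index.
    """
    _check_enumerable(n, "state enumeration")
    bits = (np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def state_index(sigma: np.ndarray) -> int:
    """Row index of ``sigma`` within :func:`all_states` of matching ``n``."""
    y = (np.asarray(sigma) > 0).astype(np.int64)
    return int(y @ (1 << np.arange(y.shape[0], dtype=np.int64)))


def log_weight(model: IsingModel, sigma: np.ndarray) -> float:
    """Unnormalised log weight ``b·σ + ½ σᵀAσ`` (diagonal of A included)."""
    s = _check_state(sigma, model.n)
    return float(model.b @ s + 0.5 * s @ model.A @ s)


def _log_weights(model: IsingModel, states: np.ndarray) -> np.ndarray:
    s = states.astype(float)
    return s @ model.b + 0.5 * np.einsum("si,ij,sj->s", s, model.A, s)


def log_partition_function(model: IsingModel) -> float:
    """``log Z`` by enumeration, accumulated in log space."""
    _check_enumerable(model.n, "partition_function")
    return float(logsumexp(_log_weights(model, all_states(model.n))))


def partition_function(model: IsingModel) -> float:
    """Partition function ``Z = Σ_σ exp(b·σ + ½σᵀAσ)`` (n ≤ 20)."""
    return float(np.exp(log_partition_function(model)))


def state_distribution(model: IsingModel) -> np.ndarray:
    """Probabilities of all ``2^n`` states, in :func:`all_states` order."""
    _check_enumerable(model.n, "state_distribution")
    lw = _log_weights(model, all_states(model.n))
    lw -= logsumexp(lw)
    return np.exp(lw)


def probability(model: IsingModel, sigma: np.ndarray) -> float:
    """Exact probability of one state (n ≤ 20); strictly positive."""
    return float(np.exp(log_weight(model, sigma) - log_partition_function(model)))


def full_conditional(
    model: IsingModel, sigma: np.ndarray, i: int, form: str = "direct"
) -> float:
    """``P(σ_i = +1 | σ_\\i)`` — a logistic regression in the rest of the state.

    ``form="direct"`` evaluates ``logistic(2(b_i + Σ_{j≠i} A_ij σ_j))``;
    ``form="spectral"`` evaluates the equivalent principal-component
    parameterisation ``logistic(2(b_i + Σ_r λ_r q_ir t_r^{(i)}))`` where
    ``t_r^{(i)}`` is the r-th principal-component rest-score (the component
    score minus ``σ_i q_ir``).  Both agree to machine precision.
    """
    s = _check_state(sigma, model.n)
    if not 0 <= i < model.n:
        raise IndexError(f"node index {i} out of range for n={model.n}")
    if form == "direct":
        field = model.b[i] + model.A[i] @ s - model.A[i, i] * s[i]
    elif form == "spectral":
        lam, Q = np.linalg.eigh(model.A)
        scores = Q.T @ s
        rest = scores - s[i] * Q[i]
        field = model.b[i] + (lam * Q[i]) @ rest
    else:
        raise ValueError(f"unknown form {form!r}")
    return float(expit(2.0 * field))


def sample_exact(model: IsingModel, N: int, seed=None) -> Dataset:
    """``N`` i.i.d. draws from the exact distribution (inverse-CDF on the
    enumerated state table; n ≤ 20)."""
    _check_enumerable(model.n, "sample_exact")
    if N < 1:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)
    p = state_distribution(model)
    idx = rng.choice(p.shape[0], size=N, p=p)
    return Dataset(all_states(model.n)[idx])


def sufficient_statistic(data: Dataset) -> np.ndarray:
    """``S = Σ_p σ_p σ_pᵀ`` — sufficient for the connectivity matrix.

    Symmetric integer matrix; diagonal entries all equal ``N``.
    """
    s = data.states.astype(np.int64)
    return s.T @ s


# ---------------------------------------------------------------------------
# delimited-text I/O (0/1 on disk, ±1 in memory)
# ---------------------------------------------------------------------------


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def load_dataset(path) -> Dataset:
    """Read a 0/1 dataset from delimited text (comma or tab, auto-detected).

    An optional first row of node labels is accepted.  Malformed content
    raises ``ValueError`` naming the file and the first bad line.
    """
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = [(no, line.rstrip("\n")) for no, line in enumerate(fh, start=1)]
    rows = [(no, line) for no, line in raw if line.strip()]
    if not rows:
        raise ValueError(f"{path}: file contains no data rows")
    delim = _detect_delimiter(rows[0][1])

    def parse(no: int, line: str) -> list[int] | None:
        out = []
        for field in line.split(delim):
            field = field.strip()
            if field in ("0", "1"):
                out.append(int(field))
            else:
                try:
                    val = float(field)
                except ValueError:
                    return None
                if val not in (0.0, 1.0):
                    raise ValueError(
                        f"{path}: line {no}: entry {field!r} is not 0 or 1"
                    )
                out.append(int(val))
        return out

    labels = None
    first = parse(*rows[0])
    if first is None:
        labels = [f.strip() for f in rows[0][1].split(delim)]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header present but no data rows")
    data = []
    width = None
    for no, line in rows:
        parsed = parse(no, line)
        if parsed is None:
            raise ValueError(f"{path}: line {no}: non-numeric entry")
        if width is None:
            width = len(parsed)
            if labels is not None and len(labels) != width:
                raise ValueError(
                    f"{path}: line {no}: {len(parsed)} columns but header has {len(labels)}"
                )
        elif len(parsed) != width:
            raise ValueError(
                f"{path}: line {no}: expected {width} columns, found {len(parsed)}"
            )
        data.append(parsed)
    y = np.asarray(data, dtype=np.int8)
    return Dataset(2 * y - 1, labels=labels)


def save_dataset(data: Dataset, path) -> None:
    """Write as comma-separated 0/1 with a header row of node labels."""
    labels = data.labels or [f"v{i}" for i in range(data.n)]
    y = ((data.states + 1) // 2).astype(np.int8)
    pd.DataFrame(y, columns=labels).to_csv(path, index=False)


def save_matrix(M: np.ndarray, path) -> None:
    """Write a numeric matrix (e.g. A, S, residuals) as comma-separated text."""
    np.savetxt(path, np.asarray(M), delimiter=",")


def load_matrix(path) -> np.ndarray:
    """Read a comma- or tab-delimited numeric matrix."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return np.atleast_2d(np.loadtxt(path, delimiter=_detect_delimiter(first)))
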