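"""Spectral machinery: diagonal shift, eigendecomposition, Eckart-Young
rank-r truncation, and the loading matrix E.

Because the diagonal of the connectivity matrix carries no information, we
may add ``shift·I`` until the matrix is positive semi-definite while leaving
every model probability untouched.  The Eckart-Young theorem then says the
best rank-r approximation (least squares) keeps the top-r eigenpairs, and
``E = Q_r Λ_r^{1/2}`` gives the loading matrix with ``E Eᵀ`` equal to that
truncation.  Loadings are the parameterisation used throughout the latent
representation and the sampler.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_SYM_TOL = 1e-10


def _check_symmetric(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix entries must be finite")
    asym = np.max(np.abs(A - A.T), initial=0.0)
    if asym > tol:
        raise ValueError(f"matrix is asymmetric beyond tolerance ({asym:.3g} > {tol:g})")
    return 0.5 * (A + A.T)


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Eigenpairs of a symmetric matrix, eigenvalues sorted descending.

    ``Q`` has orthonormal columns; each column's largest-magnitude entry is
    made positive so the decomposition is deterministic up to eigenvalue ties.
    """

    Q: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclasses.dataclass(frozen=True)
class LowRankLoadings:
    """``n × r`` loading matrix E with ``E Eᵀ`` the rank-r truncation.

    ``shift`` records the scalar that was added to the diagonal to reach
    positive semi-definiteness; column k of E has squared norm equal to the
    k-th retained eigenvalue.
    """

    E: np.ndarray
    shift: float = 0.0

    def __post_init__(self) -> None:
        E = np.atleast_2d(np.asarray(self.E, dtype=float))
        if E.ndim != 2:
            raise ValueError("E must be a matrix")
        E.setflags(write=False)
        object.__setattr__(self, "E", E)

    @property
    def n(self) -> int:
        return self.E.shape[0]

    @property
    def rank(self) -> int:
        return self.E.shape[1]


def shift_diagonal(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Add the minimal ``shift·I`` making all eigenvalues non-negative.

    Off-diagonal entries are conserved; ``shift = max(0, −λ_min(A))`` puts the
    smallest eigenvalue at exactly zero when A was indefinite.
    """
    A = _check_symmetric(A)
    lam_min = float(np.linalg.eigvalsh(A)[0])
    shift = max(0.0, -lam_min)
    return A + shift * np.eye(A.shape[0]), shift


def spectrum(A: np.ndarray) -> Spectrum:
    """Eigendecomposition with descending eigenvalues and fixed signs."""
    A = _check_symmetric(A)
    lam, Q = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    Q = Q[:, order]
    # sign convention: largest-|entry| of each eigenvector positive
    piv = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[piv, np.arange(Q.shape[1])])
    signs[signs == 0] = 1.0
    return Spectrum(Q=Q * signs, eigenvalues=lam)


def truncate(spec: Spectrum, r: int, shift: float = 0.0) -> LowRankLoadings:
    """Eckart-Young rank-r loadings ``E = Q_r diag(√λ_r)``.

    Requires the retained eigenvalues to be non-negative; a negative retained
    eigenvalue signals that :func:`shift_diagonal` was skipped.
    """
    n = spec.n
    if not 1 <= r <= n:
        raise ValueError(f"rank must satisfy 1 <= r <= n={n}, got {r}")
    lam = spec.eigenvalues[:r]
    if np.any(lam < -1e-10):
        raise ValueError(
            "retained eigenvalue is negative; apply shift_diagonal before truncating"
        )
    E = spec.Q[:, :r] * np.sqrt(np.clip(lam, 0.0, None))
    return LowRankLoadings(E=E, shift=shift)


def loadings_from_connectivity(A: np.ndarray, r: int) -> LowRankLoadings:
    """Zero the (uninformative) diagonal, shift to PSD, and truncate at rank r."""
    A = _check_symmetric(A).copy()
    np.fill_diagonal(A, 0.0)
    A_psd, shift = shift_diagonal(A)
    return truncate(spectrum(A_psd), r, shift=shift)


def reconstruct(loadings: LowRankLoadings) -> np.ndarray:
    """``E Eᵀ`` — the rank-r approximation of the (shifted) connectivity."""
    return loadings.E @ loadings.E.T


def rank_one_components(loadings: LowRankLoadings) -> list[np.ndarray]:
    """The rank-one matrices (one per retained component) summing to ``E Eᵀ``."""
    return [np.outer(loadings.E[:, k], loadings.E[:, k]) for k in range(loadings.rank)]


def save_scree(spec: Spectrum, path) -> None:
    """Write the sorted eigenvalues as two-column text (index, eigenvalue)."""
    idx = np.arange(1, spec.n + 1)
    np.savetxt(path, np.column_stack([idx, spec.eigenvalues]), fmt="%d %.12g")
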