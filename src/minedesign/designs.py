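"""Next-experiment generators for the four MINE variants, plus shared
linear-algebra utilities (modified Gram–Schmidt, symmetric inverse square
root, degenerate-eigenspace detection) and the random pilot design.

The construction behind all of the standardized variants: if ``S`` is the
symmetric inverse square root of the posterior covariance ``Gamma`` (so
``S Gamma S = I``) and ``{u_1..u_d}`` is any orthonormal set, then the batch
with rows ``x_i = S u_i`` has prediction covariance
``X Gamma X^T = U S Gamma S U^T = I_d`` — uncorrelated unit-variance
predictions, hence ``Psi = det R = 1``, the maximum of the MINE criterion.
The four variants differ only in the choice of orthonormal set and whether
the standardization is applied:

``mine_like``
    top-d eigenvectors of Gamma, *not* standardized (the naive baseline);
``mine``
    the same eigenvectors standardized by S (eigenvector v_i with eigenvalue
    lam_i maps to ``v_i / sqrt(lam_i)``);
``random_basis``
    a fresh random orthonormal set, standardized by S;
``random_rotation``
    a random rotation inside the *degenerate* top eigenspace of Gamma — the
    directions still at the prior uncertainty ceiling, i.e. the unexplored
    subspace — standardized by S.  This replaces the arbitrary (backend
    precision dependent) eigenvector choice within a tied eigenspace by an
    explicit random spin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ensemble import EnsemblePosterior

__all__ = [
    "DesignBatch",
    "OrthonormalSet",
    "EigenStructure",
    "METHODS",
    "pilot_design",
    "modified_gram_schmidt",
    "random_orthonormal_set",
    "eigen_structure",
    "inv_sqrt",
    "next_design",
]

#: the four design-generation strategies, in the order they are compared
METHODS = ("mine_like", "mine", "random_basis", "random_rotation")

#: relative eigenvalue tie tolerance defining the degenerate (unexplored)
#: eigenspace of Gamma; machine-precision ties are exactly what the random
#: rotation randomizes over
DEGENERACY_TIE_TOL = 1e-8


@dataclass
class DesignBatch:
    """A d x p matrix of next-experiment rows plus provenance."""

    rows: np.ndarray
    method: str = ""
    experiment_index: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] < 1:
            raise ValueError("a design batch needs at least one row")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("design rows must be finite")
        norms = np.linalg.norm(self.rows, axis=1)
        if np.any(norms == 0):
            bad = int(np.argmin(norms))
            raise ValueError(
                f"design row {bad} is identically zero; its prediction has no "
                "spread and the MINE criterion is undefined"
            )

    @property
    def d(self) -> int:
        return self.rows.shape[0]

    @property
    def p(self) -> int:
        return self.rows.shape[1]


@dataclass
class OrthonormalSet:
    """Rows form an orthonormal set of p-vectors (Gram matrix = identity)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        gram = self.vectors @ self.vectors.T
        if not np.allclose(gram, np.eye(self.vectors.shape[0]), atol=1e-8):
            raise ValueError("rows are not orthonormal")


@dataclass
class EigenStructure:
    """Descending eigenvalues and eigenvectors of a symmetric matrix, with the
    multiplicity of the (numerically tied) maximal eigenvalue."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns, matching order
    degenerate_count: int


# ---------------------------------------------------------------------------
# Pilot design
# ---------------------------------------------------------------------------


def pilot_design(p: int, n0: Optional[int] = None, rng: Optional[np.random.Generator] = None) -> DesignBatch:
    """Random pilot: entries i.i.d. Uniform(0, 10) / p, neither normalized nor
    orthogonalized.

    When ``n0`` is not given the sizing rule applies: 10 observations for
    ``p > 50``, otherwise a size drawn uniformly from {5,...,9}.
    """
    if not p >= 1:
        raise ValueError("p must be a positive integer")
    if rng is None:
        rng = np.random.default_rng()
    if n0 is None:
        n0 = 10 if p > 50 else int(rng.integers(5, 10))
    if n0 < 1:
        raise ValueError("pilot size must be >= 1")
    rows = rng.uniform(0.0, 10.0, size=(n0, p)) / p
    return DesignBatch(rows=rows, method="pilot", experiment_index=0)


# ---------------------------------------------------------------------------
# Linear-algebra utilities
# ---------------------------------------------------------------------------


def modified_gram_schmidt(vectors: np.ndarray) -> OrthonormalSet:
    """Orthonormalize rows by modified Gram–Schmidt, preserving the row span.

    The first output row is the normalized first input row.  Raises if a row
    is (numerically) linearly dependent on its predecessors, naming the row.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float)).copy()
    k, p = V.shape
    if k > p:
        raise ValueError(f"cannot orthonormalize {k} vectors in dimension {p}")
    out = np.empty_like(V)
    for i in range(k):
        v = V[i]
        original_norm = np.linalg.norm(v)
        # project out previously accepted directions, one at a time (MGS)
        for j in range(i):
            v = v - (out[j] @ v) * out[j]
        norm = np.linalg.norm(v)
        if norm < 1e-12 * max(original_norm, 1e-300):
            raise ValueError(
                f"row {i} is numerically linearly dependent on rows 0..{i - 1}"
            )
        out[i] = v / norm
    return OrthonormalSet(out)


def random_orthonormal_set(p: int, d: int, rng: np.random.Generator) -> OrthonormalSet:
    """d orthonormal rows drawn uniformly (Haar) in R^p: i.i.d. Gaussian rows
    orthonormalized by modified Gram–Schmidt."""
    if d > p:
        raise ValueError(f"cannot draw {d} orthonormal vectors in dimension {p}")
    raw = rng.standard_normal((d, p))
    return modified_gram_schmidt(raw)


def eigen_structure(Gamma, tie_tol: float = DEGENERACY_TIE_TOL) -> EigenStructure:
    """Descending eigendecomposition of a symmetric matrix, counting the
    eigenvalues tied with the maximum at relative tolerance ``tie_tol``.

    Accepts an :class:`EnsemblePosterior` (reusing its cached decomposition)
    or a raw symmetric matrix.
    """
    if isinstance(Gamma, EnsemblePosterior):
        lam, V = Gamma.eigendecomposition()
    else:
        G = np.asarray(Gamma, dtype=float)
        if not np.allclose(G, G.T, rtol=1e-8, atol=1e-12 * max(1.0, np.abs(G).max())):
            raise ValueError("matrix is not symmetric within tolerance")
        lam, V = np.linalg.eigh(G)
        lam, V = lam[::-1], np.ascontiguousarray(V[:, ::-1])
        from .ensemble import _fix_eigvec_signs

        V = _fix_eigvec_signs(V)
    lam_max = lam[0]
    degenerate = int(np.count_nonzero(lam_max - lam <= tie_tol * abs(lam_max)))
    return EigenStructure(eigenvalues=lam, eigenvectors=V, degenerate_count=max(degenerate, 1))


def inv_sqrt(Gamma) -> np.ndarray:
    """Symmetric inverse square root ``S`` of an SPD matrix: ``S Gamma S = I``."""
    es = eigen_structure(Gamma)
    lam = es.eigenvalues
    if lam[-1] <= 1e-14 * lam[0]:
        raise ValueError(
            "matrix is numerically singular (eigenvalue ratio below 1e-14); "
            "inverse square root is ill conditioned"
        )
    V = es.eigenvectors
    S = (V / np.sqrt(lam)) @ V.T
    return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# Next-experiment generation
# ---------------------------------------------------------------------------


def _standardize(rows: np.ndarray, lam: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Apply S = V diag(1/sqrt(lam)) V^T to each row without forming S."""
    return ((rows @ V) / np.sqrt(lam)) @ V.T


def next_design(
    post: EnsemblePosterior,
    d: int,
    method: str,
    rng: Optional[np.random.Generator] = None,
    experiment_index: int = 0,
    seed: Optional[int] = None,
    tie_tol: float = DEGENERACY_TIE_TOL,
) -> DesignBatch:
    """Generate the next d-row design batch under one of the four variants.

    For the three standardized variants (``mine``, ``random_basis``,
    ``random_rotation``) the returned batch has prediction covariance
    ``X Gamma X^T = I_d`` and therefore ``Psi = 1``, the criterion maximum.
    """
    if method not in METHODS:
        raise ValueError(f"unknown design method {method!r}; expected one of {METHODS}")
    if d > post.p:
        raise ValueError(f"cannot design d={d} rows with only p={post.p} coefficients")
    if method in ("random_basis", "random_rotation") and rng is None:
        raise ValueError(f"method {method!r} requires a random generator")

    es = eigen_structure(post, tie_tol=tie_tol)
    lam, V = es.eigenvalues, es.eigenvectors

    if method == "mine_like":
        rows = V[:, :d].T.copy()
    elif method == "mine":
        # S v_i = v_i / sqrt(lam_i) for an eigenvector
        rows = (V[:, :d] / np.sqrt(lam[:d])).T.copy()
    elif method == "random_basis":
        U = random_orthonormal_set(post.p, d, rng).vectors
        rows = _standardize(U, lam, V)
    else:  # random_rotation
        g = es.degenerate_count
        k = min(d, g)
        # A random orthonormal k-frame in the degenerate (unexplored)
        # eigenspace: distributionally the first k rows of a Haar g x g
        # rotation applied to the degenerate eigenvectors.
        Q = random_orthonormal_set(g, k, rng).vectors  # k x g
        rotated = Q @ V[:, :g].T  # k x p, still inside the degenerate span
        rows = _standardize(rotated, lam, V)
        if k < d:
            # unexplored subspace smaller than the batch: pad with the
            # next-largest (non-degenerate) eigenvectors, standardized
            extra = (V[:, g:d] / np.sqrt(lam[g:d])).T
            rows = np.vstack([rows, extra])

    return DesignBatch(rows=rows, method=method, experiment_index=experiment_index, seed=seed)
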