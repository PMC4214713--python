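"""Classical model-refinement (D-optimality) criterion and its relation to MINE.

Model refinement chooses the next batch ``X_new`` to sharpen the estimates of
an assumed model: it maximizes the determinant of the information matrix of
the augmented design.  With the prior-regularized Gram matrix
``G = X^T X + b I`` (which keeps everything finite in the ``n < p`` regime),
the gain factor of a candidate batch is

    phi = det(X_aug^T X_aug + b I) / det(X^T X + b I)
        = det(I_d + X_new G^{-1} X_new^T),

where the second form is the matrix determinant identity actually computed.
``phi >= 1`` always (the added Gram term is PSD) and ``log phi`` is additive
over sequentially appended batches.

The equivalence with MINE: maximize ``det(I_d + X_new Gamma X_new^T)``
subject to each planned prediction having unit ensemble variance
(``diag(X_new Gamma X_new^T) = 1``).  Any standardized-orthonormal-basis
design achieves the maximum ``2^d``, and no feasible design exceeds it —
under the shared constraint the MINE-optimal designs are exactly the
D-optimal ones.  :func:`verify_doptimal_equivalence` checks both halves numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .ensemble import DataSet, EnsemblePosterior
from .designs import next_design

__all__ = ["RefinementValue", "refinement_value", "refinement_gradient", "verify_doptimal_equivalence"]


@dataclass
class RefinementValue:
    phi: float
    log_phi: float


def _rows_of(batch) -> np.ndarray:
    rows = np.asarray(getattr(batch, "rows", batch), dtype=float)
    if rows.size == 0:
        return rows.reshape(0, rows.shape[-1] if rows.ndim == 2 else 0)
    return np.atleast_2d(rows)


def _regularized_gram_cho(data: DataSet, b: float):
    if not b > 0:
        raise ValueError("b must be positive")
    G = data.X.T @ data.X
    G[np.diag_indices_from(G)] += b
    return sla.cho_factor(G, lower=True)


def refinement_value(data: DataSet, b: float, batch) -> RefinementValue:
    """Determinant gain ``phi = det(I_d + X_new (X^T X + b I)^{-1} X_new^T)``.

    An empty batch gives ``phi = 1``.
    """
    rows = _rows_of(batch)
    if rows.shape[0] == 0:
        return RefinementValue(phi=1.0, log_phi=0.0)
    if rows.shape[1] != data.p:
        raise ValueError(
            f"batch has {rows.shape[1]} columns but the data have p={data.p}"
        )
    cho = _regularized_gram_cho(data, b)
    W = sla.cho_solve(cho, rows.T)  # G^{-1} X_new^T
    M = np.eye(rows.shape[0]) + rows @ W
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise RuntimeError("refinement factor is not positive; matrix degenerate")
    return RefinementValue(phi=float(np.exp(logdet)), log_phi=float(logdet))


def refinement_gradient(data: DataSet, b: float, batch) -> np.ndarray:
    """Gradient of ``phi`` with respect to every entry of ``X_new``.

    With ``M = I + X_new G^{-1} X_new^T``:
    ``d phi / d X_new = 2 phi M^{-1} X_new G^{-1}`` (a d x p matrix).  For a
    single row x this reduces to ``2 phi G^{-1} x / (1 + x^T G^{-1} x)``.
    """
    rows = _rows_of(batch)
    if rows.shape[0] == 0:
        return np.zeros_like(rows)
    if rows.shape[1] != data.p:
        raise ValueError(
            f"batch has {rows.shape[1]} columns but the data have p={data.p}"
        )
    cho = _regularized_gram_cho(data, b)
    W = sla.cho_solve(cho, rows.T)  # G^{-1} X_new^T, p x d
    M = np.eye(rows.shape[0]) + rows @ W
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise RuntimeError("refinement factor is not positive; matrix degenerate")
    phi = float(np.exp(logdet))
    return 2.0 * phi * np.linalg.solve(M, W.T)


def verify_doptimal_equivalence(
    post: EnsemblePosterior,
    d: int,
    rng: np.random.Generator,
    n_trials: int = 200,
) -> dict:
    """Numerically verify the D-optimality/MINE equivalence.

    Checks that (a) a standardized-orthonormal-basis design attains the
    constrained refinement factor ``det(I_d + X Gamma X^T) = 2^d``, and
    (b) ``n_trials`` random designs satisfying the constraint
    ``diag(X Gamma X^T) = 1`` never exceed ``2^d``.
    """
    if d > post.p:
        raise ValueError("d must not exceed p")
    bound = 2.0**d

    batch = next_design(post, d, "random_basis", rng)
    F = np.eye(d) + batch.rows @ post.Gamma @ batch.rows.T
    standardized_factor = float(np.linalg.det(F))

    max_random = -np.inf
    for _ in range(n_trials):
        X = rng.standard_normal((d, post.p))
        # rescale every row to unit prediction variance: x^T Gamma x = 1
        var = np.einsum("ij,jk,ik->i", X, post.Gamma, X)
        X = X / np.sqrt(var)[:, None]
        F = np.eye(d) + X @ post.Gamma @ X.T
        max_random = max(max_random, float(np.linalg.det(F)))

    return {
        "d": d,
        "bound": bound,
        "standardized_factor": standardized_factor,
        "standardized_ok": abs(standardized_factor - bound) <= 1e-6 * bound,
        "max_random_factor": max_random,
        "n_trials": n_trials,
        "random_within_bound": max_random <= bound * (1 + 1e-6),
    }
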