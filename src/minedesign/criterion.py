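"""The MINE design criterion: how informative is a candidate next experiment?

For a candidate batch ``X_new`` (d rows of planned observations) and the
current coefficient ensemble with covariance ``Gamma``, the predicted
responses across the ensemble have covariance

    D = X_new Gamma X_new^T                     (d x d, PSD)

Normalizing D to a correlation matrix R and taking its determinant gives the
MINE criterion

    Psi = det R,    0 <= Psi <= 1,

the squared volume of the prism spanned by the normalized predictions.
``Psi = 1`` iff the predictions are mutually uncorrelated — the batch probes d
independent directions of remaining uncertainty — and ``Psi = 0`` iff the
predictions are linearly dependent.  By the Hadamard inequality
``det D <= prod_i D_ii``, and the gap ``det D / prod D_ii`` equals Psi, so the
criterion measures exactly the dependence among predictions and is invariant
to rescaling any design row by a positive constant (scale-free).
"""

from __future__ import annotations

import numpy as np

from .ensemble import EnsemblePosterior, NumericalDegeneracyError

__all__ = [
    "prediction_covariance",
    "correlation_from_covariance",
    "psi_mine",
    "hadamard_gap",
]

# relative eigenvalue floor below which a correlation matrix counts as singular
_SINGULAR_REL = 1e-12


def _batch_rows(batch) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(getattr(batch, "rows", batch), dtype=float))
    return rows


def prediction_covariance(post: EnsemblePosterior, batch) -> np.ndarray:
    """Covariance ``X_new Gamma X_new^T`` of the batch predictions.

    Computed through the eigendecomposition of ``Gamma`` when the posterior
    has one cached: with ``T = X_new V``, ``D = T diag(lam) T^T`` sums only
    non-negative diagonal terms, which stays PSD even when the design rows are
    large enough that the direct triple product loses the tiny eigenvalues of
    ``Gamma`` to round-off.
    """
    rows = _batch_rows(batch)
    if rows.shape[1] != post.p:
        raise ValueError(
            f"design rows have {rows.shape[1]} columns, posterior has p={post.p}"
        )
    if post._eig is not None:
        lam, V = post.eigendecomposition()
        T = rows @ V
        D = (T * lam) @ T.T
    else:
        D = rows @ post.Gamma @ rows.T
    return 0.5 * (D + D.T)


def correlation_from_covariance(D: np.ndarray) -> np.ndarray:
    """Normalize a PSD covariance to a correlation matrix with unit diagonal."""
    D = np.asarray(D, dtype=float)
    diag = np.diag(D)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise NumericalDegeneracyError(
            f"prediction variance is not positive for design row {bad}; "
            "a (near-)zero row has no prediction spread and the criterion "
            "is undefined for it"
        )
    s = 1.0 / np.sqrt(diag)
    R = D * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R


def _det_correlation(R: np.ndarray) -> float:
    """det of a correlation matrix via Cholesky; eigenvalue fallback near rank
    deficiency (the regime where predictions are almost linearly dependent)."""
    try:
        L = np.linalg.cholesky(R)
        return float(np.prod(np.diag(L)) ** 2)
    except np.linalg.LinAlgError:
        ev = np.linalg.eigvalsh(R)
        top = ev[-1]
        if top <= 0:
            return 0.0
        ev = np.clip(ev, 0.0, None)
        if np.any(ev < _SINGULAR_REL * top):
            return 0.0
        return float(np.prod(ev))


def psi_mine(post: EnsemblePosterior, batch) -> float:
    """The MINE criterion ``Psi = det R`` for a candidate batch; in [0, 1]."""
    D = prediction_covariance(post, batch)
    return _det_correlation(correlation_from_covariance(D))


def hadamard_gap(D: np.ndarray) -> float:
    """Ratio ``det D / prod_i D_ii`` in [0, 1]; equals Psi of the same D.

    Computed on the log scale from ``slogdet``, an independent route from the
    correlation-matrix Cholesky used by :func:`psi_mine`.
    """
    D = np.asarray(D, dtype=float)
    diag = np.diag(D)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise NumericalDegeneracyError(
            f"diagonal entry {bad} of the prediction covariance is not positive"
        )
    sign, logdet = np.linalg.slogdet(D)
    if sign <= 0:
        return 0.0
    return float(np.exp(logdet - np.sum(np.log(diag))))
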