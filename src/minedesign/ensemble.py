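"""Gaussian ensemble (conjugate posterior) for the linear model with known noise.

The linear model is ``y = X beta + eps`` with ``eps ~ N(0, sigma^2 I)`` and a
zero-mean conjugate Gaussian prior whose precision matrix is ``b/sigma^2 I``
(the scaled-conjugate form of Box & Tiao: the prior width tracks the noise
scale, ``beta ~ N(0, (sigma^2/b) I)``).  The "ensemble" of coefficient
vectors consistent with the data — the posterior — is then exactly Gaussian
with

    Gamma = sigma^2 (X^T X + b I)^{-1}          (posterior covariance)
    mu    = (X^T X + b I)^{-1} X^T y            (posterior mean)

i.e. the ridge solution of the normal equations with its classical sampling
covariance, well defined even when ``n < p`` where X^T X is rank deficient.
The posterior is never computed through a generalized inverse: the precision
matrix is symmetric positive definite for any ``b > 0`` and is factorized
directly.  With no data the ensemble is the prior: ``mu = 0`` and
``Gamma = (sigma^2/b) I``.

Significance of individual coefficients uses the known-variance z statistic
``z_i = mu_i / sqrt(Gamma_ii)`` with two-sided standard-normal p-values and a
Benjamini–Hochberg step-up correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "NumericalDegeneracyError",
    "TruthConfig",
    "DataSet",
    "EnsemblePosterior",
    "SignificanceReport",
    "fit_posterior",
    "posterior_from_stats",
    "update_posterior",
    "significance_test",
    "bh_stepup",
]


class NumericalDegeneracyError(RuntimeError):
    """Raised when a matrix that must be positive definite numerically is not."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TruthConfig:
    """Generative ground truth and study parameters for a simulated design study.

    Parameters
    ----------
    p
        Number of regression coefficients.
    beta_true
        Length-``p`` true coefficient vector (typically sparse).
    sigma
        Error standard deviation (known to the analyst).
    b
        Prior precision scale (the ridge constant): the prior is
        ``N(0, (sigma^2/b) I)``.  The tail-bound rule calibrates ``1/sqrt(b)``
        to the largest anticipated coefficient magnitude (see
        :func:`minedesign.prior.choose_b`).
    d
        Observations added per designed experiment (the batch size).
    n_experiments
        Number of post-pilot experiments in a replicate.
    pilot_size
        Number of pilot observations; ``None`` means "apply the default pilot
        sizing rule" (10 observations when ``p > 50``, otherwise a number drawn
        uniformly from 5–9).
    alpha
        Benjamini–Hochberg significance level.
    seed
        Non-negative study seed; all replicate randomness derives from it.
    """

    p: int
    beta_true: np.ndarray
    sigma: float
    b: float
    d: int = 10
    n_experiments: int = 99
    pilot_size: Optional[int] = None
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if not (isinstance(self.p, (int, np.integer)) and self.p >= 1):
            raise ValueError("p must be a positive integer")
        if self.beta_true.shape != (self.p,):
            raise ValueError(
                f"beta_true must have exactly p={self.p} entries, "
                f"got shape {self.beta_true.shape}"
            )
        if not np.all(np.isfinite(self.beta_true)):
            raise ValueError("beta_true must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.b > 0:
            raise ValueError("b must be positive")
        if not (1 <= self.d <= self.p):
            raise ValueError("d must satisfy 1 <= d <= p")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be a positive integer")
        if self.pilot_size is not None and self.pilot_size < 1:
            raise ValueError("pilot_size must be >= 1 when given")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        self.seed = int(self.seed)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta_true))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthConfig):
            return NotImplemented
        return (
            self.p == other.p
            and np.array_equal(self.beta_true, other.beta_true)
            and self.sigma == other.sigma
            and self.b == other.b
            and self.d == other.d
            and self.n_experiments == other.n_experiments
            and self.pilot_size == other.pilot_size
            and self.alpha == other.alpha
            and self.seed == other.seed
        )


@dataclass
class DataSet:
    """All observations gathered so far: design matrix ``X`` and responses ``y``.

    ``n < p`` is the expected regime; rank deficiency of X^T X is not an error.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.size == 0:
            # normalize the empty representation to (0, p)
            p = self.X.shape[1] if self.X.ndim == 2 and self.X.shape[1] else 0
            self.X = self.X.reshape(0, p)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("X and y must contain only finite values")

    @classmethod
    def empty(cls, p: int) -> "DataSet":
        return cls(np.empty((0, p)), np.empty(0))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def append(self, new_X: np.ndarray, new_y: np.ndarray) -> "DataSet":
        new_X = np.atleast_2d(np.asarray(new_X, dtype=float))
        new_y = np.asarray(new_y, dtype=float).ravel()
        if new_X.shape[0] == 0:
            return DataSet(self.X, self.y)
        if new_X.shape[1] != self.p:
            raise ValueError(
                f"new rows have {new_X.shape[1]} columns, expected p={self.p}"
            )
        return DataSet(np.vstack([self.X, new_X]), np.concatenate([self.y, new_y]))


@dataclass
class EnsemblePosterior:
    """Moments of the Gaussian ensemble over regression coefficients.

    ``mu`` is the posterior mean and ``Gamma`` the posterior covariance; with
    no data the ensemble is the prior: ``mu = 0`` and ``Gamma = (sigma^2/b) I``.

    The instance caches sufficient statistics (X^T X, X^T y) so sequential
    updates are exact, and lazily caches the eigendecomposition of ``Gamma``
    (eigenvalues descending) which the design generators reuse.
    """

    mu: np.ndarray
    Gamma: np.ndarray
    n_obs: int
    sigma: float
    b: float
    # sufficient statistics for exact sequential updating (internal)
    _A: Optional[np.ndarray] = field(default=None, repr=False)
    _c: Optional[np.ndarray] = field(default=None, repr=False)
    # cached eigendecomposition of Gamma: (eigenvalues desc, eigenvectors cols)
    _eig: Optional[tuple] = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def eigendecomposition(self) -> tuple:
        """Eigenvalues (descending) and matching eigenvector columns of Gamma.

        Eigenvector signs follow the convention that the first component of
        non-negligible magnitude is positive, for backend-independent output.
        """
        if self._eig is None:
            lam, V = np.linalg.eigh(self.Gamma)
            lam, V = lam[::-1], V[:, ::-1]
            V = _fix_eigvec_signs(V)
            self._eig = (lam, V)
        return self._eig


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the first non-negligible entry is positive."""
    mags = np.abs(V)
    thresh = 1e-12 * mags.max(axis=0, keepdims=True)
    first = np.argmax(mags > thresh, axis=0)
    signs = np.sign(V[first, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class SignificanceReport:
    """Per-coefficient z-values, two-sided normal p-values and BH decisions."""

    z: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.significant))


# ---------------------------------------------------------------------------
# Posterior computation
# ---------------------------------------------------------------------------


def posterior_from_stats(
    A: np.ndarray, c: np.ndarray, n_obs: int, sigma: float, b: float
) -> EnsemblePosterior:
    """Posterior from sufficient statistics ``A = X^T X`` and ``c = X^T y``.

    A single symmetric eigendecomposition of the regularized Gram matrix
    ``A + b I`` yields the covariance ``Gamma = sigma^2 (A + b I)^{-1}``, the
    mean ``mu = (A + b I)^{-1} c`` and (cached) the eigenstructure of
    ``Gamma`` used downstream by the design generators.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not b > 0:
        raise ValueError("b must be positive")
    A = np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    p = c.shape[0]
    if A.shape != (p, p):
        raise ValueError("A must be p x p matching the length of c")

    G = A.copy()
    G[np.diag_indices_from(G)] += b
    w, V = np.linalg.eigh(G)  # ascending eigenvalues of X^T X + bI, all >= b
    if not np.all(np.isfinite(w)):
        raise NumericalDegeneracyError("non-finite eigenvalues in the Gram matrix")
    if w[0] < -1e-8 * w[-1]:
        # beyond eigh round-off on a PSD-plus-ridge matrix: genuinely bad input
        raise NumericalDegeneracyError(
            f"regularized Gram matrix not positive definite (min eigenvalue {w[0]:.3e})"
        )
    # X^T X is PSD, so exact eigenvalues of X^T X + bI are >= b; values below b
    # are floating-point round-off (the Gram matrix can dwarf b) and are clamped
    np.clip(w, b, None, out=w)
    mu = V @ ((V.T @ c) / w)
    Gamma = sigma**2 * ((V / w) @ V.T)
    Gamma = 0.5 * (Gamma + Gamma.T)
    # Gamma eigenvalues are sigma^2/w; w ascending so this is already descending
    lam = sigma**2 / w
    Veig = _fix_eigvec_signs(V)
    post = EnsemblePosterior(mu=mu, Gamma=Gamma, n_obs=int(n_obs), sigma=float(sigma), b=float(b))
    post._A = A
    post._c = c
    post._eig = (lam, Veig)
    return post


def fit_posterior(data: DataSet, sigma: float, b: float) -> EnsemblePosterior:
    """Fit the Gaussian ensemble to all observations in ``data``.

    With no data the result is the prior (``mu = 0``, ``Gamma = (1/b) I``).
    The result is identical (to numerical tolerance) whether computed in one
    shot or via :func:`update_posterior` on any partition of the rows.
    """
    if not isinstance(data, DataSet):
        data = DataSet(*data)
    A = data.X.T @ data.X
    c = data.X.T @ data.y
    return posterior_from_stats(A, c, data.n, sigma, b)


def update_posterior(
    post: EnsemblePosterior, new_X: np.ndarray, new_y: np.ndarray
) -> EnsemblePosterior:
    """Incorporate a new batch of observations into the ensemble.

    Equivalent to refitting on the concatenated data; the batch may be empty
    (returning an identical posterior).
    """
    new_X = np.atleast_2d(np.asarray(new_X, dtype=float))
    new_y = np.asarray(new_y, dtype=float).ravel()
    if new_X.shape[0] == 0:
        return post
    if new_X.shape[1] != post.p:
        raise ValueError(f"new rows have {new_X.shape[1]} columns, expected {post.p}")
    if new_X.shape[0] != new_y.shape[0]:
        raise ValueError("row count of new_X must match length of new_y")
    if not np.all(np.isfinite(new_X)) or not np.all(np.isfinite(new_y)):
        raise ValueError("new observations must be finite")
    if post._A is None or post._c is None:
        # reconstruct sufficient statistics from the moments:
        # A + bI = sigma^2 Gamma^{-1}, c = (A + bI) mu
        lam, V = post.eigendecomposition()
        Ginv = (V / lam) @ V.T  # Gamma^{-1}
        A = post.sigma**2 * Ginv - post.b * np.eye(post.p)
        c = post.sigma**2 * (Ginv @ post.mu)
    else:
        A, c = post._A, post._c
    A = A + new_X.T @ new_X
    c = c + new_X.T @ new_y
    return posterior_from_stats(A, c, post.n_obs + new_X.shape[0], post.sigma, post.b)


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------


def bh_stepup(pvals: Sequence[float], alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at FDR level ``alpha``.

    Sort the m p-values ascending, find the largest k with
    ``p_(k) <= k * alpha / m``, and reject the k smallest; the decision vector
    is returned in the original order.  Ties share the decision of the largest
    qualifying rank, which the step-up rule handles automatically under a
    stable sort.
    """
    pvals = np.asarray(pvals, dtype=float).ravel()
    m = pvals.shape[0]
    if m == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= thresholds)[0]
    significant = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1
        significant[order[:k]] = True
    return significant


def significance_test(post: EnsemblePosterior, alpha: float) -> SignificanceReport:
    """Known-variance z-test with BH correction on every coefficient.

    ``z_i = mu_i / sqrt(Gamma_ii)``; p-values are two-sided standard-normal
    tail probabilities (the error variance is known, so no t correction).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    diag = np.diag(post.Gamma)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise NumericalDegeneracyError(
            f"non-positive posterior variance at coefficient {bad}"
        )
    z = post.mu / np.sqrt(diag)
    pvals = 2.0 * _stats.norm.sf(np.abs(z))
    return SignificanceReport(
        z=z, pvals=pvals, significant=bh_stepup(pvals, alpha), alpha=float(alpha)
    )
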