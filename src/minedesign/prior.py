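"""Choosing the prior precision scale b.

The prior ``beta ~ N(0, (1/b) I)`` acts like a fishing net cast over
coefficient space: it must be wide enough that the true coefficients are not
far out in its tails, or the data will struggle to pull the posterior toward
them.  Two constraints guide the choice:

* tail bound — the prior standard deviation ``1/sqrt(b)`` should be at least
  the largest anticipated coefficient magnitude (equality allowed; e.g. a
  largest magnitude of 50 gives ``b = 1/50^2 = 4e-4``);
* data dominance — per eigendirection of ``X^T X`` with eigenvalue
  ``lambda_i``, the posterior uncertainty ``1/sqrt(lambda_i + b)`` must not
  exceed the prior uncertainty ``1/sqrt(b)``.  This holds automatically for
  any ``lambda_i >= 0`` and is the looser of the two constraints; it is
  checked as a sanity invariant.

b must also not be so small that the regularized Gram matrix becomes
numerically singular (the ridge-regression role of the prior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import DataSet

__all__ = ["PriorDiagnostics", "choose_b", "check_prior"]


@dataclass
class PriorDiagnostics:
    b: float
    lambda_max: float
    tail_bound_ok: bool
    data_dominance_ok: bool


def choose_b(beta_max_magnitude: float) -> float:
    """Prior precision ``b = 1 / beta_max^2``: the prior standard deviation
    equals the largest anticipated coefficient magnitude.

    Strictly decreasing in ``beta_max_magnitude``.
    """
    if not beta_max_magnitude > 0:
        raise ValueError("beta_max_magnitude must be positive")
    return 1.0 / beta_max_magnitude**2


def check_prior(data: DataSet, b: float, beta_max_magnitude: float) -> PriorDiagnostics:
    """Check the tail-bound and data-dominance constraints for a given b."""
    if not b > 0:
        raise ValueError("b must be positive")
    if not beta_max_magnitude > 0:
        raise ValueError("beta_max_magnitude must be positive")
    if data.n == 0:
        lambda_max = 0.0
        lambdas = np.zeros(1)
    else:
        lambdas = np.linalg.eigvalsh(data.X.T @ data.X)
        lambdas = np.clip(lambdas, 0.0, None)  # clip eigh round-off below zero
        lambda_max = float(lambdas[-1])
    prior_sd = 1.0 / np.sqrt(b)
    # equality at the bound passes (b set exactly at 1/beta_max^2)
    tail_ok = bool(prior_sd >= beta_max_magnitude * (1 - 1e-12))
    dominance_ok = bool(np.all(1.0 / np.sqrt(lambdas + b) <= prior_sd * (1 + 1e-12)))
    return PriorDiagnostics(
        b=float(b),
        lambda_max=lambda_max,
        tail_bound_ok=tail_ok,
        data_dominance_ok=dominance_ok,
    )
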