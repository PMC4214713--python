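"""Replicated sequential-design studies under a known sparse truth.

Each replicate runs the full discovery cycle: a random pilot, then a loop of
(design the next batch from the current posterior -> simulate its responses
from the true model -> update the posterior -> test every coefficient with a
BH-corrected z-test).  Per experiment the replicate records how many truly
nonzero coefficients were declared significant (true discoveries), how many
truly zero ones were (false positives), the MINE criterion value of the
chosen batch, and the posterior means of a tracked index window.

Random-stream discipline: each replicate draws its pilot design and pilot
responses from a *pilot stream* seeded by (study seed, replicate index) only,
so all design methods see bit-identical pilots within a replicate — the
comparison between methods is then purely about what they do after the pilot.
Everything post-pilot comes from a *method stream* additionally keyed by the
method label.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    NumericalDegeneracyError,
    TruthConfig,
    posterior_from_stats,
    significance_test,
)
from .designs import METHODS, next_design, pilot_design
from .criterion import psi_mine

__all__ = [
    "ReplicateTrajectory",
    "StudyResult",
    "generate_response",
    "run_replicate",
    "run_study",
    "summarize_power_fpr",
    "milestone",
]


def _method_code(method: str) -> int:
    # stable across processes and Python versions, unlike hash()
    return zlib.crc32(method.encode("utf-8")) & 0x7FFFFFFF


def _pilot_stream(truth: TruthConfig, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([truth.seed, replicate]))


def _method_stream(truth: TruthConfig, replicate: int, method: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed, replicate, _method_code(method)])
    )


@dataclass
class ReplicateTrajectory:
    """Per-experiment records for one replicate of one method."""

    method: str
    replicate: int
    experiment: np.ndarray  # 1..n_experiments
    n_true_significant: np.ndarray
    n_false_positive: np.ndarray
    psi: np.ndarray
    tracked_means: np.ndarray  # n_experiments x n_tracked
    pilot_digest: str
    n_nonzero: int
    p: int

    def __post_init__(self) -> None:
        if np.any(self.n_true_significant < 0) or np.any(
            self.n_true_significant > self.n_nonzero
        ):
            raise ValueError("true-significant counts out of range")
        n_null = self.p - self.n_nonzero
        if np.any(self.n_false_positive < 0) or np.any(self.n_false_positive > n_null):
            raise ValueError("false-positive counts out of range")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "replicate": self.replicate,
                "experiment": self.experiment,
                "n_true_sig": self.n_true_significant,
                "n_false_pos": self.n_false_positive,
                "psi": self.psi,
            }
        )
        for j in range(self.tracked_means.shape[1]):
            df[f"mu_{j + 1}"] = self.tracked_means[:, j]
        return df


@dataclass
class StudyResult:
    """Aggregated trajectories for one method across replicates.

    ``true_sig_counts`` and ``false_pos_counts`` are (replicates x
    experiments) matrices, so power at any discovery threshold k can be
    derived after the fact; ``ks`` holds the default thresholds (70/80/90/100%
    of the truly nonzero count, the milestones used in the comparisons).
    """

    method: str
    n_replicates: int
    p: int
    n_nonzero: int
    experiments: np.ndarray
    true_sig_counts: np.ndarray
    false_pos_counts: np.ndarray
    mean_psi: np.ndarray
    mean_tracked: np.ndarray
    replicates: List[int] = field(default_factory=list)
    failed_replicates: List[int] = field(default_factory=list)

    @property
    def ks(self) -> List[int]:
        m = self.n_nonzero
        return sorted({int(np.ceil(f * m)) for f in (0.7, 0.8, 0.9, 1.0)})

    def power(self, k: int) -> np.ndarray:
        """Fraction of replicates with >= k true discoveries, per experiment."""
        if not (1 <= k <= self.n_nonzero):
            raise ValueError(f"k must be in 1..{self.n_nonzero}")
        return (self.true_sig_counts >= k).mean(axis=0)

    @property
    def mean_false_positives(self) -> np.ndarray:
        return self.false_pos_counts.mean(axis=0)

    @property
    def fpr_percent(self) -> np.ndarray:
        """Mean false positives as a percent of the truly-zero coefficients."""
        return 100.0 * self.mean_false_positives / (self.p - self.n_nonzero)


def generate_response(
    batch, beta_true: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate responses ``y = X_new beta_true + sigma * z``, z iid N(0,1)."""
    rows = np.atleast_2d(np.asarray(getattr(batch, "rows", batch), dtype=float))
    beta_true = np.asarray(beta_true, dtype=float)
    if rows.shape[1] != beta_true.shape[0]:
        raise ValueError("design columns must match the length of beta_true")
    noise = sigma * rng.standard_normal(rows.shape[0]) if sigma > 0 else 0.0
    return rows @ beta_true + noise


def run_replicate(
    truth: TruthConfig,
    method: str,
    replicate: int,
    n_tracked: int = 20,
) -> ReplicateTrajectory:
    """One full sequential-design replicate under a known truth.

    Deterministic given (truth.seed, replicate, method); the pilot depends
    only on (truth.seed, replicate), so all methods share pilots.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    n_tracked = min(n_tracked, truth.p)
    nonzero = truth.beta_true != 0

    pilot_rng = _pilot_stream(truth, replicate)
    pilot = pilot_design(truth.p, truth.pilot_size, pilot_rng)
    y_pilot = generate_response(pilot, truth.beta_true, truth.sigma, pilot_rng)
    digest = hashlib.sha256(
        np.ascontiguousarray(pilot.rows).tobytes() + np.ascontiguousarray(y_pilot).tobytes()
    ).hexdigest()

    method_rng = _method_stream(truth, replicate, method)

    A = pilot.rows.T @ pilot.rows
    c = pilot.rows.T @ y_pilot
    n = pilot.rows.shape[0]

    n_exp = truth.n_experiments
    n_true = np.zeros(n_exp, dtype=int)
    n_false = np.zeros(n_exp, dtype=int)
    psis = np.zeros(n_exp)
    tracked = np.zeros((n_exp, n_tracked))

    i = -1  # experiment index for error reporting; -1 = pilot fit
    try:
        post = posterior_from_stats(A, c, n, truth.sigma, truth.b)
        for i in range(n_exp):
            batch = next_design(
                post, truth.d, method, method_rng, experiment_index=i + 1, seed=truth.seed
            )
            psis[i] = psi_mine(post, batch)
            y_new = generate_response(batch, truth.beta_true, truth.sigma, method_rng)
            A += batch.rows.T @ batch.rows
            c += batch.rows.T @ y_new
            n += truth.d
            post = posterior_from_stats(A, c, n, truth.sigma, truth.b)
            report = significance_test(post, truth.alpha)
            n_true[i] = int(np.count_nonzero(report.significant & nonzero))
            n_false[i] = int(np.count_nonzero(report.significant & ~nonzero))
            tracked[i] = post.mu[:n_tracked]
    except NumericalDegeneracyError as err:
        raise NumericalDegeneracyError(
            f"replicate {replicate}, method {method!r}, experiment {i + 1}: {err}"
        ) from err

    return ReplicateTrajectory(
        method=method,
        replicate=replicate,
        experiment=np.arange(1, n_exp + 1),
        n_true_significant=n_true,
        n_false_positive=n_false,
        psi=psis,
        tracked_means=tracked,
        pilot_digest=digest,
        n_nonzero=truth.n_nonzero,
        p=truth.p,
    )


def _aggregate(
    truth: TruthConfig, method: str, trajs: Sequence[ReplicateTrajectory], failed: List[int]
) -> StudyResult:
    if failed and len(failed) > 0.01 * (len(trajs) + len(failed)):
        raise RuntimeError(
            f"{len(failed)} of {len(trajs) + len(failed)} replicates failed "
            f"numerically for method {method!r}; refusing to aggregate"
        )
    return StudyResult(
        method=method,
        n_replicates=len(trajs),
        p=truth.p,
        n_nonzero=truth.n_nonzero,
        experiments=np.arange(1, truth.n_experiments + 1),
        true_sig_counts=np.stack([t.n_true_significant for t in trajs]),
        false_pos_counts=np.stack([t.n_false_positive for t in trajs]),
        mean_psi=np.stack([t.psi for t in trajs]).mean(axis=0),
        mean_tracked=np.stack([t.tracked_means for t in trajs]).mean(axis=0),
        replicates=[t.replicate for t in trajs],
        failed_replicates=list(failed),
    )


def run_study(
    truth: TruthConfig,
    methods: Sequence[str],
    n_replicates: int,
    workers: int = 1,
    n_tracked: int = 20,
    return_trajectories: bool = False,
) -> dict:
    """Run ``n_replicates`` replicates of each method and aggregate.

    Returns ``{method: StudyResult}`` (and, if ``return_trajectories``, a
    second dict of the raw per-replicate trajectories).  Pilot equality across
    methods is asserted per replicate.  Aggregation is keyed by replicate
    index, so the result is independent of the worker count.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")

    jobs = [(m, r) for m in methods for r in range(n_replicates)]

    def _one(m: str, r: int):
        try:
            return run_replicate(truth, m, r, n_tracked=n_tracked)
        except NumericalDegeneracyError as err:
            return (m, r, str(err))

    if workers > 1:
        from joblib import Parallel, delayed

        outputs = Parallel(n_jobs=workers)(delayed(_one)(m, r) for m, r in jobs)
    else:
        outputs = [_one(m, r) for m, r in jobs]

    by_method: dict = {m: [] for m in methods}
    failed: dict = {m: [] for m in methods}
    for out in outputs:
        if isinstance(out, tuple):
            m, r, _msg = out
            failed[m].append(r)
        else:
            by_method[out.method].append(out)

    # shared-pilot contract: identical pilot digests across methods
    if len(methods) > 1:
        digests = {}
        for m in methods:
            for t in by_method[m]:
                ref = digests.setdefault(t.replicate, t.pilot_digest)
                if t.pilot_digest != ref:
                    raise AssertionError(
                        f"pilot for replicate {t.replicate} differs between methods"
                    )

    results = {m: _aggregate(truth, m, by_method[m], failed[m]) for m in methods}
    if return_trajectories:
        return results, by_method
    return results


def summarize_power_fpr(
    result: StudyResult, k: int, experiment_indices: Sequence[int]
) -> pd.DataFrame:
    """Power (>= k true discoveries) and false-positive percentages at the
    requested experiment indices, both on the 0-100 scale."""
    rows = []
    power = result.power(k)
    fpr = result.fpr_percent
    for e in experiment_indices:
        if not (1 <= e <= result.experiments[-1]):
            raise ValueError(f"experiment index {e} outside 1..{result.experiments[-1]}")
        rows.append(
            {
                "experiment": e,
                "power_percent": 100.0 * power[e - 1],
                "fpr_percent": fpr[e - 1],
            }
        )
    return pd.DataFrame(rows)


def milestone(result: StudyResult, k: int, threshold: float) -> Optional[int]:
    """First experiment index at which the fraction of replicates with >= k
    true discoveries reaches ``threshold``; None if never reached."""
    power = result.power(k)
    hits = np.nonzero(power >= threshold)[0]
    return int(result.experiments[hits[0]]) if hits.size else None
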