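"""Configuration parsing, presets, fixtures and deterministic serialization.

Configs are YAML (JSON is accepted too, being a YAML subset).  All numeric
output uses a fixed 10-significant-digit format so trajectory files diff
reproducibly across runs and platforms.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .ensemble import DataSet, SignificanceReport, TruthConfig
from .prior import choose_b
from .simulate import ReplicateTrajectory, StudyResult

__all__ = [
    "BENCHMARK_PRESET_NAME",
    "benchmark_preset",
    "load_config",
    "serialize_config",
    "make_fixture",
    "read_dataset",
    "write_dataset",
    "write_significance",
    "write_trajectories",
    "write_summary",
    "write_manifest",
    "config_hash",
]

_FMT = "%.10g"

BENCHMARK_PRESET_NAME = "benchmark-1000"

# The standard benchmark truth: 1000 coefficients, the first ten nonzero with
# magnitudes up to 50, batch size 10, known noise sd 0.01, BH at 1%, prior sd
# 50 (b = 1/2500).
_PRESET_NONZERO = [11.0, -36.0, -26.0, 9.0, 33.0, -50.0, -45.0, 15.0, 3.0, 17.0]


def benchmark_preset(
    seed: int = 0,
    sigma: float = 0.01,
    n_experiments: int = 99,
) -> TruthConfig:
    """The packaged 1000-coefficient benchmark configuration."""
    beta = np.zeros(1000)
    beta[:10] = _PRESET_NONZERO
    return TruthConfig(
        p=1000,
        beta_true=beta,
        sigma=sigma,
        b=choose_b(50.0),
        d=10,
        n_experiments=n_experiments,
        pilot_size=10,
        alpha=0.01,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_REQUIRED = ("p", "beta_true", "sigma")
_KNOWN = _REQUIRED + ("b", "d", "n_experiments", "pilot_size", "alpha", "seed")


def load_config(path: Union[str, Path]) -> TruthConfig:
    """Load and validate a study configuration from YAML/JSON.

    Defaults: ``d=10``, ``alpha=0.01``, ``n_experiments=99``, ``seed=0``;
    ``b`` defaults to ``choose_b(max |beta_true|)``; ``pilot_size`` left unset
    applies the pilot sizing rule at run time.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    problems = []
    for key in _REQUIRED:
        if key not in raw:
            problems.append(f"missing required field {key!r}")
    for key in raw:
        if key not in _KNOWN:
            problems.append(f"unknown field {key!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    beta = np.asarray(raw["beta_true"], dtype=float)
    b = raw.get("b")
    if b is None:
        mags = np.abs(beta)
        if mags.max() <= 0:
            raise ValueError(f"{path}: b must be given when beta_true is all zero")
        b = choose_b(float(mags.max()))
    try:
        return TruthConfig(
            p=int(raw["p"]),
            beta_true=beta,
            sigma=float(raw["sigma"]),
            b=float(b),
            d=int(raw.get("d", 10)),
            n_experiments=int(raw.get("n_experiments", 99)),
            pilot_size=None if raw.get("pilot_size") is None else int(raw["pilot_size"]),
            alpha=float(raw.get("alpha", 0.01)),
            seed=int(raw.get("seed", 0)),
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def _config_dict(cfg: TruthConfig) -> dict:
    return {
        "p": cfg.p,
        "beta_true": [float(v) for v in cfg.beta_true],
        "sigma": cfg.sigma,
        "b": cfg.b,
        "d": cfg.d,
        "n_experiments": cfg.n_experiments,
        "pilot_size": cfg.pilot_size,
        "alpha": cfg.alpha,
        "seed": cfg.seed,
    }


def serialize_config(cfg: TruthConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: TruthConfig) -> str:
    canonical = json.dumps(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def make_fixture(p: int, n_nonzero: int, scale: float, seed: int) -> TruthConfig:
    """Deterministic sparse truth for tests and small studies.

    The first ``n_nonzero`` coefficients are nonzero with magnitudes drawn
    uniformly in [scale/10, scale] and seeded random signs; ``b`` is set by
    the tail-bound rule from ``scale``.
    """
    if n_nonzero > p:
        raise ValueError("n_nonzero must not exceed p")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    if n_nonzero:
        mags = rng.uniform(scale / 10.0, scale, size=n_nonzero)
        signs = rng.choice([-1.0, 1.0], size=n_nonzero)
        beta[:n_nonzero] = mags * signs
    return TruthConfig(
        p=p,
        beta_true=beta,
        sigma=0.01,
        b=choose_b(scale),
        d=min(10, p),
        n_experiments=30,
        pilot_size=None,
        alpha=0.01,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Tabular artifacts
# ---------------------------------------------------------------------------


def write_dataset(data: DataSet, path: Union[str, Path]) -> None:
    """Headered TSV with columns x1..xp then y."""
    df = pd.DataFrame(data.X, columns=[f"x{i + 1}" for i in range(data.p)])
    df["y"] = data.y
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_dataset(path: Union[str, Path]) -> DataSet:
    df = pd.read_csv(path, sep="\t")
    if "y" not in df.columns:
        raise ValueError(f"{path}: missing 'y' column")
    xcols = [c for c in df.columns if c != "y"]
    return DataSet(df[xcols].to_numpy(float), df["y"].to_numpy(float))


def write_significance(
    report: SignificanceReport, mu: np.ndarray, sd: np.ndarray, path: Union[str, Path]
) -> None:
    """Posterior summary TSV: index, mu, sd, z, pval, significant."""
    df = pd.DataFrame(
        {
            "index": np.arange(1, mu.shape[0] + 1),
            "mu": mu,
            "sd": sd,
            "z": report.z,
            "pval": report.pvals,
            "significant": report.significant.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def write_trajectories(
    trajs: Sequence[ReplicateTrajectory], path: Union[str, Path], compress: bool = True
) -> Path:
    """Per-replicate trajectory records as (optionally gzipped) TSV."""
    path = Path(path)
    df = pd.concat([t.to_frame() for t in trajs], ignore_index=True)
    if compress and not path.name.endswith(".gz"):
        path = path.with_name(path.name + ".gz")
    text = df.to_csv(sep="\t", index=False, float_format=_FMT)
    if path.name.endswith(".gz"):
        # fixed mtime and no embedded filename, for byte-identical re-runs
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as fh:
                fh.write(text.encode())
    else:
        path.write_text(text)
    return path


def write_summary(result: StudyResult, path: Union[str, Path]) -> None:
    """Study summary TSV: per experiment, power at each default threshold k,
    mean false positives and the false-positive percentage."""
    cols = {"experiment": result.experiments}
    for k in result.ks:
        cols[f"power_ge_{k}"] = result.power(k)
    cols["mean_false_positives"] = result.mean_false_positives
    cols["fpr_percent"] = result.fpr_percent
    cols["mean_psi"] = result.mean_psi
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FMT)


def write_manifest(
    cfg: TruthConfig,
    methods: Sequence[str],
    n_replicates: int,
    path: Union[str, Path],
    extra: Optional[dict] = None,
) -> None:
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "config": _config_dict(cfg),
        "methods": list(methods),
        "n_replicates": n_replicates,
        "replicate_seeds": [[cfg.seed, r] for r in range(n_replicates)],
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
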