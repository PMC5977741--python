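"""Synthetic matrix-trial generator with Tucker-structured class signal.

Each class c has a discriminative core G_c (K x K); trial n of class c is

    X_n = U1 (G_c + E_n) U2' + V1 H_n V2' + S_n,

with E_n, H_n i.i.d. normal core noise, U1 (J1 x K), U2 (J2 x K) the
discriminative mode components, V1, V2 independent components carrying
structured but non-discriminative noise shared across classes, and S_n a
full-rank i.i.d. sensor-noise floor.  Without the sensor floor every trial
would live in a ~2K-dimensional subspace per mode and vectorised LDA would
never face the singular regime that motivates multilinear methods; real
recordings always carry broadband measurement noise.  Defaults emulate a
10-channel x 80-sample trial with K = 3 components per mode and three nominal
signal levels scaling the between-class core difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import TensorDataset, random_orthonormal

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "replicate_study", "SIGNAL_LEVELS"]

#: nominal signal-level multipliers on the class-core difference
SIGNAL_LEVELS = {"low": 0.5, "medium": 1.0, "high": 2.0}


@dataclass
class SimConfig:
    dims: tuple[int, int] = (10, 80)
    K: int = 3
    n_train: int = 100  # per class
    n_test: int = 100  # per class
    signal_level: str = "medium"
    signal_scale: Optional[float] = None  # overrides signal_level if set
    core_noise_sd: float = 1.0
    structured_noise_sd: float = 1.0
    sensor_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K > min(self.dims):
            raise ValueError(f"K={self.K} exceeds min dim of {self.dims}")
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("counts must be >= 1 train, >= 0 test per class")
        if self.core_noise_sd <= 0 or min(self.structured_noise_sd, self.sensor_noise_sd) < 0:
            raise ValueError("noise standard deviations must be positive")
        if self.signal_scale is None and self.signal_level not in SIGNAL_LEVELS:
            raise ValueError(f"signal_level must be one of {sorted(SIGNAL_LEVELS)}")

    @property
    def scale(self) -> float:
        return (
            self.signal_scale
            if self.signal_scale is not None
            else SIGNAL_LEVELS[self.signal_level]
        )


@dataclass
class SimTruth:
    class_cores: np.ndarray  # (2, K, K)
    U1: np.ndarray  # J1 x K
    U2: np.ndarray  # J2 x K
    V1: np.ndarray
    V2: np.ndarray
    core_noise_sd: float
    structured_noise_sd: float
    sensor_noise_sd: float


def _emit(
    rng: np.random.Generator, truth: SimTruth, n_per_class: int
) -> TensorDataset:
    xs, ys = [], []
    j1, j2 = truth.U1.shape[0], truth.U2.shape[0]
    for c in (0, 1):
        G = truth.class_cores[c]
        k = G.shape[0]
        for _ in range(n_per_class):
            E = truth.core_noise_sd * rng.standard_normal((k, k))
            H = truth.structured_noise_sd * rng.standard_normal((k, k))
            S = truth.sensor_noise_sd * rng.standard_normal((j1, j2))
            xs.append(
                truth.U1 @ (G + E) @ truth.U2.T + truth.V1 @ H @ truth.V2.T + S
            )
            ys.append(c)
    return TensorDataset(np.stack(xs), np.array(ys))


def simulate_dataset(cfg: SimConfig) -> tuple[TensorDataset, TensorDataset, SimTruth]:
    """Draw ground truth and balanced train/test sets.

    Class cores are a shared standard-normal base plus/minus half the scaled
    core difference; mode components are orthonormalised Gaussian matrices.
    Train and test trials come from distinct RNG streams of the same truth.
    """
    j1, j2 = cfg.dims
    rng_truth = np.random.default_rng(cfg.seed)
    base = rng_truth.standard_normal((cfg.K, cfg.K))
    delta = rng_truth.standard_normal((cfg.K, cfg.K))
    cores = np.stack(
        [base + 0.5 * cfg.scale * delta, base - 0.5 * cfg.scale * delta]
    )
    truth = SimTruth(
        class_cores=cores,
        U1=random_orthonormal(rng_truth, j1, cfg.K),
        U2=random_orthonormal(rng_truth, j2, cfg.K),
        V1=random_orthonormal(rng_truth, j1, cfg.K),
        V2=random_orthonormal(rng_truth, j2, cfg.K),
        core_noise_sd=cfg.core_noise_sd,
        structured_noise_sd=cfg.structured_noise_sd,
        sensor_noise_sd=cfg.sensor_noise_sd,
    )
    train = _emit(np.random.default_rng((cfg.seed, 1)), truth, cfg.n_train)
    test = (
        _emit(np.random.default_rng((cfg.seed, 2)), truth, cfg.n_test)
        if cfg.n_test > 0
        else train
    )
    return train, test, truth


def replicate_study(
    methods: dict[str, "MethodFactory"],
    n_train_grid: Sequence[int] = (50, 100, 200),
    signal_level: str = "medium",
    reps: int = 25,
    seed: int = 0,
    base_config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Held-out AUC over a replicate x n_train x method grid.

    For each replicate a fresh truth is drawn, every method is fitted on the
    training trials and scored on the independent test trials.  Returns a
    long-format frame (replicate, n_train, method, auc, train_auc, error);
    method failures are recorded per cell, not fatal.
    """
    from .evaluate import auc as auc_fn  # local import to avoid cycle

    base = base_config or SimConfig()
    rows = []
    for rep in range(reps):
        for n_train in n_train_grid:
            cfg = SimConfig(
                dims=base.dims,
                K=base.K,
                n_train=n_train,
                n_test=base.n_test,
                signal_level=signal_level,
                signal_scale=base.signal_scale,
                core_noise_sd=base.core_noise_sd,
                structured_noise_sd=base.structured_noise_sd,
                sensor_noise_sd=base.sensor_noise_sd,
                seed=seed + 1_000_003 * rep + 17 * n_train,
            )
            train, test, _ = simulate_dataset(cfg)
            for name, factory in methods.items():
                row = {"replicate": rep, "n_train": n_train, "method": name}
                try:
                    fitted = factory(train, cfg.seed + 31)
                    row["auc"] = auc_fn(fitted.score(test), test.y)
                    row["train_auc"] = auc_fn(fitted.train_scores, train.y)
                    row["error"] = ""
                except Exception as err:  # recorded, not fatal
                    row["auc"] = np.nan
                    row["train_auc"] = np.nan
                    row["error"] = f"{type(err).__name__}: {err}"
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC plus/minus the standard error of the mean per grid cell."""
    g = table.groupby(["method", "n_train"])["auc"]
    out = g.agg(mean_auc="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"].clip(lower=1))
    return out
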