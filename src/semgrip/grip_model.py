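"""Grip-force regression: Random Forest tuned by bald eagle search.

The model maps per-window sEMG feature vectors to grip force in %MVC.  Two
Random Forest hyperparameters are tuned — ``n_estimators`` and
``min_samples_leaf`` — by minimizing a fitness that sums the training-set
and test-set mean squared errors of a forest fitted with the candidate
parameters.  Note that this fitness deliberately includes the test split
(that is how the tuning objective is defined here); a cross-validated
variant that never touches the held-out split is available via
``cv_folds`` for leakage-free tuning.

Evaluation metrics, for true forces f_i, predictions p_i and N pairs:

    MAE = (1/N) sum |f_i - p_i|
    MSE = (1/N) sum (f_i - p_i)^2
    R^2 = 1 - sum (p_i - f_i)^2 / sum (f_i - mean f)^2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split

from .bes import BESConfig, optimize
from .errors import ConfigError

__all__ = [
    "Dataset",
    "SplitConfig",
    "HyperparamSpace",
    "FitnessEvaluation",
    "PredictionSet",
    "EvaluationReport",
    "split",
    "rf_fitness",
    "tune",
    "TuneResult",
    "evaluate",
    "train_final",
    "predict",
    "save_model",
    "load_model",
    "tune_train_evaluate",
]


@dataclass
class Dataset:
    """Feature matrix with %MVC force labels (one row per window)."""

    X: pd.DataFrame
    y: pd.Series
    subjects: pd.Series | None = None

    def __post_init__(self) -> None:
        self.X = pd.DataFrame(self.X)
        self.y = pd.Series(np.asarray(self.y, dtype=float), index=self.X.index)
        if len(self.X) != len(self.y) or len(self.X) == 0:
            raise ConfigError("X and y must be non-empty and equally long")
        if not np.all(np.isfinite(self.X.to_numpy(dtype=float))):
            raise ConfigError("X contains non-finite entries")
        if not np.all(np.isfinite(self.y.to_numpy())):
            raise ConfigError("y contains non-finite entries")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame) -> "Dataset":
        """Build from the features module's table (label column percent_mvc)."""
        cols = [c for c in table.columns if c not in ("percent_mvc", "window_start")]
        return cls(X=table[cols], y=table["percent_mvc"])


@dataclass(frozen=True)
class SplitConfig:
    """Random row-wise train/test split (70/30 by default)."""

    train_fraction: float = 0.70
    seed: int = 0
    stratify_by_subject: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie in (0, 1)")


def split(ds: Dataset, cfg: SplitConfig | None = None) -> tuple[Dataset, Dataset]:
    """Seeded random partition into train/test subsets.

    With ``stratify_by_subject`` the split is stratified on subject ids so
    each subject contributes proportionally to both sides.
    """
    cfg = cfg or SplitConfig()
    if len(ds) < 10:
        raise ConfigError(f"need at least 10 rows to split, got {len(ds)}")
    strat = ds.subjects if (cfg.stratify_by_subject and ds.subjects is not None) else None
    idx_train, idx_test = train_test_split(
        np.arange(len(ds)),
        train_size=cfg.train_fraction,
        random_state=cfg.seed,
        stratify=strat,
    )
    def take(idx: np.ndarray) -> Dataset:
        return Dataset(
            X=ds.X.iloc[idx],
            y=ds.y.iloc[idx],
            subjects=None if ds.subjects is None else ds.subjects.iloc[idx],
        )
    return take(idx_train), take(idx_test)


@dataclass(frozen=True)
class HyperparamSpace:
    """Integer box for (n_estimators, min_samples_leaf)."""

    n_estimators: tuple[int, int] = (10, 500)
    min_samples_leaf: tuple[int, int] = (1, 20)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("n_estimators", self.n_estimators),
            ("min_samples_leaf", self.min_samples_leaf),
        ):
            if lo < 1 or lo > hi:
                raise ConfigError(f"{name} bounds must satisfy 1 <= lo <= hi")

    def round_point(self, point: Sequence[float]) -> tuple[int, int]:
        """Continuous BES position -> integer parameter pair (half rounds up)."""
        n = int(np.clip(np.floor(point[0] + 0.5), *self.n_estimators))
        leaf = int(np.clip(np.floor(point[1] + 0.5), *self.min_samples_leaf))
        return n, leaf


@dataclass
class FitnessEvaluation:
    """Train/test predictions and the summed-MSE fitness of one RF fit."""

    n_estimators: int
    min_samples_leaf: int
    t_sim1: np.ndarray  # predictions on the training set
    t_sim2: np.ndarray  # predictions on the test set
    mse_train: float
    mse_test: float

    @property
    def fitness(self) -> float:
        return self.mse_train + self.mse_test


def _make_rf(n_estimators: int, min_samples_leaf: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )


def rf_fitness(
    params: Sequence[float],
    train: Dataset,
    test: Dataset,
    seed: int = 0,
    space: HyperparamSpace | None = None,
) -> FitnessEvaluation:
    """Fit an RF with the candidate parameters; fitness = MSE_train + MSE_test."""
    space = space or HyperparamSpace()
    n, leaf = space.round_point(params)
    rf = _make_rf(n, leaf, seed)
    rf.fit(train.X, train.y)
    t1 = rf.predict(train.X)
    t2 = rf.predict(test.X)
    return FitnessEvaluation(
        n_estimators=n,
        min_samples_leaf=leaf,
        t_sim1=t1,
        t_sim2=t2,
        mse_train=float(np.mean((train.y.to_numpy() - t1) ** 2)),
        mse_test=float(np.mean((test.y.to_numpy() - t2) ** 2)),
    )


def _cv_fitness(
    params: Sequence[float],
    train: Dataset,
    seed: int,
    space: HyperparamSpace,
    folds: int,
) -> float:
    """Leakage-free alternative: mean validation MSE over K folds of train."""
    n, leaf = space.round_point(params)
    mses = []
    for tr_idx, va_idx in KFold(folds, shuffle=True, random_state=seed).split(train.X):
        rf = _make_rf(n, leaf, seed)
        rf.fit(train.X.iloc[tr_idx], train.y.iloc[tr_idx])
        pred = rf.predict(train.X.iloc[va_idx])
        mses.append(float(np.mean((train.y.iloc[va_idx].to_numpy() - pred) ** 2)))
    return float(np.mean(mses))


@dataclass
class TuneResult:
    """Best integer parameter pair, its fitness, and the BES history."""

    n_estimators: int
    min_samples_leaf: int
    best_fitness: float
    history: list[float]
    evaluations: dict[tuple[int, int], float] = field(default_factory=dict)


def tune(
    train: Dataset,
    test: Dataset,
    space: HyperparamSpace | None = None,
    bes_cfg: BESConfig | None = None,
    rf_seed: int = 0,
    cv_folds: int | None = None,
) -> TuneResult:
    """Minimize the RF fitness over the hyperparameter box with BES.

    BES works on the continuous relaxation of the integer box; positions are
    rounded at evaluation and results cached per integer pair, so repeated
    visits to the same pair cost nothing.  Defaults follow the best-observed
    optimizer setting: population 10, 30 iterations.
    """
    space = space or HyperparamSpace()
    bes_cfg = bes_cfg or BESConfig(
        pop_size=10,
        max_iter=30,
        lo=(space.n_estimators[0], space.min_samples_leaf[0]),
        hi=(space.n_estimators[1], space.min_samples_leaf[1]),
    )
    cache: dict[tuple[int, int], float] = {}

    def fitness(point: np.ndarray) -> float:
        key = space.round_point(point)
        if key not in cache:
            if cv_folds:
                cache[key] = _cv_fitness(point, train, rf_seed, space, cv_folds)
            else:
                cache[key] = rf_fitness(point, train, test, rf_seed, space).fitness
        return cache[key]

    result = optimize(fitness, bes_cfg)
    n, leaf = space.round_point(result.best_position)
    return TuneResult(
        n_estimators=n,
        min_samples_leaf=leaf,
        best_fitness=result.best_fitness,
        history=result.history,
        evaluations=cache,
    )


@dataclass
class PredictionSet:
    """Paired true/predicted grip forces."""

    f_true: np.ndarray
    f_pred: np.ndarray

    def __post_init__(self) -> None:
        self.f_true = np.asarray(self.f_true, dtype=float)
        self.f_pred = np.asarray(self.f_pred, dtype=float)
        if self.f_true.shape != self.f_pred.shape or self.f_true.ndim != 1:
            raise ConfigError("f_true and f_pred must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.f_true.size


@dataclass(frozen=True)
class EvaluationReport:
    """MAE / MSE / R-squared of a prediction set."""

    mae: float
    mse: float
    r2: float


def evaluate(p: PredictionSet) -> EvaluationReport:
    """Compute MAE, MSE and R^2 from paired true/predicted forces."""
    if len(p) == 0:
        raise ConfigError("cannot evaluate an empty prediction set")
    err = p.f_true - p.f_pred
    ss_tot = float(np.sum((p.f_true - p.f_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigError("R^2 is undefined when the true forces are constant")
    return EvaluationReport(
        mae=float(np.mean(np.abs(err))),
        mse=float(np.mean(err ** 2)),
        r2=1.0 - float(np.sum(err ** 2)) / ss_tot,
    )


def train_final(
    train: Dataset, n_estimators: int, min_samples_leaf: int, seed: int = 0
) -> RandomForestRegressor:
    """Fit the final forest on the training split with the tuned parameters."""
    rf = _make_rf(n_estimators, min_samples_leaf, seed)
    rf.fit(train.X, train.y)
    return rf


def predict(model: RandomForestRegressor, ds: Dataset) -> PredictionSet:
    """Predict held-out forces and pair them with the truth."""
    return PredictionSet(f_true=ds.y.to_numpy(), f_pred=model.predict(ds.X))


def save_model(model: RandomForestRegressor, path: str | Path, meta: dict | None = None) -> None:
    """Persist a fitted model with its metadata (params, seed) to one file."""
    joblib.dump({"model": model, "meta": meta or {}}, path)


def load_model(path: str | Path) -> tuple[RandomForestRegressor, dict]:
    blob = joblib.load(path)
    return blob["model"], blob.get("meta", {})


def tune_train_evaluate(
    ds: Dataset,
    split_cfg: SplitConfig | None = None,
    space: HyperparamSpace | None = None,
    bes_cfg: BESConfig | None = None,
    rf_seed: int = 0,
    cv_folds: int | None = None,
) -> tuple[TuneResult, EvaluationReport, PredictionSet]:
    """The full modelling workflow: split, tune, refit, score held-out data."""
    train, test = split(ds, split_cfg)
    tuned = tune(train, test, space, bes_cfg, rf_seed, cv_folds)
    model = train_final(train, tuned.n_estimators, tuned.min_samples_leaf, rf_seed)
    preds = predict(model, test)
    return tuned, evaluate(preds), preds
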