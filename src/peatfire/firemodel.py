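"""Fortnightly fire-count regression with paired feed-forward networks.

Both model variants share one architecture: a four-layer fully connected
network (input, hidden 32, hidden 16, linear output) with relu hidden
activations, trained on mean squared error with Adam at learning rate
0.001 and early stopping.  Training and validation follow a
leave-one-year-out scheme: each calendar year is held out in turn, a
network is fitted on the remaining years, and out-of-sample predictions
for the held-out year are collected so that every record is predicted
exactly once by a model that never saw it.

Features are z-scored using statistics of the training years only.  Raw
network outputs can be slightly negative; predictions are clipped at
zero, since fire counts are nonnegative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

__all__ = ["NetworkSpec", "TrainedFold", "SpecError", "build_network",
           "train_loocv", "predict", "save_folds", "load_folds"]

VALID_WIDTHS = (6, 8)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    n_features: int
    hidden: tuple[int, int] = (32, 16)
    activation: str = "relu"
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    max_epochs: int = 500
    patience: int = 20
    validation_fraction: float = 0.1
    batch_size: int = 256
    seed: int = 0

    @property
    def layer_sizes(self) -> list[int]:
        return [self.n_features, *self.hidden, 1]


@dataclass
class TrainedFold:
    """One leave-one-year-out fold: the held-out year never contributes to
    either the scaler statistics or the fitted weights."""

    held_out_year: int
    model: MLPRegressor
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    n_features: int
    epochs_run: int
    seed: int
    feature_names: list[str] = field(default_factory=list)


def build_network(n_features: int) -> NetworkSpec:
    """Network specification for a 6-feature (weather-only) or 8-feature
    (weather+hydrology) input."""
    if n_features not in VALID_WIDTHS:
        raise SpecError(f"input width must be one of {VALID_WIDTHS}, got {n_features}")
    return NetworkSpec(n_features=n_features)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), []


def _fit_one(Xtr: np.ndarray, ytr: np.ndarray, spec: NetworkSpec, seed: int) -> MLPRegressor:
    model = MLPRegressor(
        hidden_layer_sizes=spec.hidden,
        activation=spec.activation,
        solver=spec.optimizer,
        learning_rate_init=spec.learning_rate,
        max_iter=spec.max_epochs,
        early_stopping=True,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=spec.patience,
        # early stopping carves the validation split out of Xtr first
        batch_size=min(spec.batch_size,
                       max(1, int(len(Xtr) * (1 - spec.validation_fraction)))),
        random_state=seed,
    )
    model.fit(Xtr, ytr)
    return model


def train_loocv(X, y, years, spec: NetworkSpec | None = None
                ) -> tuple[list[TrainedFold], np.ndarray]:
    """Leave-one-year-out training.

    Returns one fold per distinct year plus the out-of-sample prediction
    for every record (from the fold that held out its year).  Results are
    deterministic for a given ``spec.seed``.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    years = np.asarray(years)
    if np.isnan(Xm).any():
        raise ValueError("design matrix contains NaN")
    if np.isnan(y).any():
        raise ValueError("target contains NaN")
    if spec is None:
        spec = build_network(Xm.shape[1])
    if Xm.shape[1] != spec.n_features:
        raise SpecError(f"X has {Xm.shape[1]} columns but spec expects {spec.n_features}")
    unique_years = np.unique(years)
    if len(unique_years) < 2:
        raise ValueError("leave-one-year-out needs at least 2 distinct years")

    folds: list[TrainedFold] = []
    oos = np.full(len(y), np.nan)
    for k, held in enumerate(unique_years):
        train = years != held
        mean = Xm[train].mean(axis=0)
        scale = Xm[train].std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        seed = int((spec.seed * 1009 + k) % (2**31 - 1))
        model = _fit_one((Xm[train] - mean) / scale, y[train], spec, seed)
        fold = TrainedFold(
            held_out_year=int(held), model=model, scaler_mean=mean,
            scaler_scale=scale, n_features=spec.n_features,
            epochs_run=int(model.n_iter_), seed=seed, feature_names=names,
        )
        folds.append(fold)
        oos[~train] = predict(fold, Xm[~train])
    return folds, oos


def predict(fold: TrainedFold, X) -> np.ndarray:
    """Nonnegative fire-count predictions from one fitted fold."""
    Xm, _ = _as_matrix(X)
    if Xm.ndim != 2 or Xm.shape[1] != fold.n_features:
        raise SpecError(
            f"X has shape {Xm.shape}, fold expects {fold.n_features} features"
        )
    raw = fold.model.predict((Xm - fold.scaler_mean) / fold.scaler_scale)
    return np.clip(raw, 0.0, None)


# ---------------------------------------------------------------------------
# Serialization: JSON metadata with nested weight arrays (portable, text)
# ---------------------------------------------------------------------------

def save_folds(folds: list[TrainedFold], path) -> None:
    payload = []
    for f in folds:
        payload.append({
            "held_out_year": f.held_out_year,
            "n_features": f.n_features,
            "epochs_run": f.epochs_run,
            "seed": f.seed,
            "feature_names": f.feature_names,
            "scaler_mean": f.scaler_mean.tolist(),
            "scaler_scale": f.scaler_scale.tolist(),
            "coefs": [w.tolist() for w in f.model.coefs_],
            "intercepts": [b.tolist() for b in f.model.intercepts_],
        })
    Path(path).write_text(json.dumps(payload))


def load_folds(path) -> list[TrainedFold]:
    payload = json.loads(Path(path).read_text())
    folds = []
    for item in payload:
        spec = build_network(item["n_features"])
        model = MLPRegressor(hidden_layer_sizes=spec.hidden, activation=spec.activation,
                             solver=spec.optimizer, max_iter=1)
        # rebuild the fitted attributes without retraining
        model.coefs_ = [np.asarray(w) for w in item["coefs"]]
        model.intercepts_ = [np.asarray(b) for b in item["intercepts"]]
        model.n_layers_ = len(model.coefs_) + 1
        model.n_outputs_ = 1
        model.out_activation_ = "identity"
        folds.append(TrainedFold(
            held_out_year=item["held_out_year"], model=model,
            scaler_mean=np.asarray(item["scaler_mean"]),
            scaler_scale=np.asarray(item["scaler_scale"]),
            n_features=item["n_features"], epochs_run=item["epochs_run"],
            seed=item["seed"], feature_names=item["feature_names"],
        ))
    return folds
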