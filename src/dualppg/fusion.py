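"""MLP regression mapping window feature vectors to SBP or DBP.

A two-hidden-layer perceptron (80 and 12 units, ReLU, 20% dropout after each
hidden layer, mean-squared-error loss, Adam at learning rate 0.001) trained on
z-scored features with early stopping on a held-out validation set.  The
network is implemented directly on numpy so that dropout, the externally
supplied validation split, best-weights restoration, and full per-seed
determinism are all under explicit control; at this parameter count (~1600
weights) mini-batch numpy is fast.

Feature scaling is fitted on the training rows only — validation and test
rows pass through the frozen transform — and targets are internally z-scored
for optimizer conditioning, with predictions mapped back to mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_model import ValidationError

__all__ = [
    "MLPConfig",
    "FeatureScaler",
    "TrainedModel",
    "fit_scaler",
    "train_model",
    "predict_bp",
    "save_model",
    "load_model",
]


@dataclass
class MLPConfig:
    """Architecture and training schedule of the fusion network."""

    hidden_sizes: tuple[int, int] = (80, 12)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 32
    early_stop_patience: int = 30
    seed: int = 0

    def validate(self) -> None:
        if len(self.hidden_sizes) != 2:
            raise ValidationError("hidden_sizes must name exactly two layers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be >= 1")


@dataclass
class FeatureScaler:
    """Per-feature z-scoring statistics learned from training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.mean.size:
            raise ValidationError(
                f"scaler expects {self.mean.size} features, got {X.shape[1]}"
            )
        return (X - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=np.float64) * self.sd + self.mean


def fit_scaler(X: np.ndarray, feature_names: tuple[str, ...] | None = None) -> FeatureScaler:
    """Fit z-scoring statistics; constant columns are rejected by name."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("scaler needs a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        names = (
            ", ".join(feature_names[i] for i in bad)
            if feature_names
            else ", ".join(f"column {i}" for i in bad)
        )
        raise ValidationError(f"constant feature(s) cannot be scaled: {names}")
    return FeatureScaler(mean=mean, sd=sd, feature_names=feature_names)


# --------------------------------------------------------------------------
# The network
# --------------------------------------------------------------------------

class _Net:
    """Plain two-hidden-layer MLP with inverted dropout and Adam."""

    def __init__(self, n_in: int, cfg: MLPConfig, rng: np.random.Generator):
        h1, h2 = cfg.hidden_sizes
        # He initialisation for the ReLU layers, small-variance linear head
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, h1))
        self.b1 = np.zeros(h1)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h1), size=(h1, h2))
        self.b2 = np.zeros(h2)
        self.W3 = rng.normal(0.0, np.sqrt(1.0 / h2), size=(h2, 1))
        self.b3 = np.zeros(1)
        self._adam_m = [np.zeros_like(p) for p in self.params()]
        self._adam_v = [np.zeros_like(p) for p in self.params()]
        self._adam_t = 0

    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s

    def forward(self, X: np.ndarray) -> np.ndarray:
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        return (a2 @ self.W3 + self.b3).ravel()

    def train_batch(
        self, X: np.ndarray, y: np.ndarray, cfg: MLPConfig, rng: np.random.Generator
    ) -> float:
        n = X.shape[0]
        keep = 1.0 - cfg.dropout_rate
        z1 = X @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        if cfg.dropout_rate > 0:
            m1 = (rng.random(a1.shape) < keep) / keep
            a1 = a1 * m1
        z2 = a1 @ self.W2 + self.b2
        a2 = np.maximum(z2, 0.0)
        if cfg.dropout_rate > 0:
            m2 = (rng.random(a2.shape) < keep) / keep
            a2 = a2 * m2
        yhat = (a2 @ self.W3 + self.b3).ravel()
        err = yhat - y
        loss = float(np.mean(err**2))

        g_out = (2.0 / n) * err[:, None]
        gW3 = a2.T @ g_out
        gb3 = g_out.sum(axis=0)
        g2 = g_out @ self.W3.T
        if cfg.dropout_rate > 0:
            g2 = g2 * m2
        g2 = g2 * (z2 > 0)
        gW2 = a1.T @ g2
        gb2 = g2.sum(axis=0)
        g1 = g2 @ self.W2.T
        if cfg.dropout_rate > 0:
            g1 = g1 * m1
        g1 = g1 * (z1 > 0)
        gW1 = X.T @ g1
        gb1 = g1.sum(axis=0)

        self._adam_t += 1
        b1c, b2c = 0.9, 0.999
        lr = cfg.learning_rate
        grads = [gW1, gb1, gW2, gb2, gW3, gb3]
        for p, g, m, v in zip(self.params(), grads, self._adam_m, self._adam_v):
            m[...] = b1c * m + (1 - b1c) * g
            v[...] = b2c * v + (1 - b2c) * g**2
            mhat = m / (1 - b1c**self._adam_t)
            vhat = v / (1 - b2c**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
        return loss


@dataclass
class TrainedModel:
    """A fitted fusion model: network weights + scalers + training history."""

    target: str
    net: _Net
    scaler: FeatureScaler
    config: MLPConfig
    y_mean: float
    y_sd: float
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.net.W1.shape[0]


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: MLPConfig | None = None,
    target: str = "SBP",
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Train the fusion MLP with validation-based early stopping.

    Deterministic for a fixed config seed: weight initialisation, epoch
    shuffling, and dropout masks all draw from one generator seeded with
    ``cfg.seed``.  Training stops at ``max_epochs`` or once validation MSE has
    not improved for ``early_stop_patience`` epochs; the best-validation
    weights are restored.  History records per-epoch train/validation MSE in
    mmHg^2.
    """
    cfg = cfg or MLPConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    X_val = np.asarray(X_val, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64).ravel()
    if X.shape[0] != y.size or X_val.shape[0] != y_val.size:
        raise ValidationError("row counts of features and targets must match")
    if X_val.shape[1] != X.shape[1]:
        raise ValidationError("validation width must match training width")

    scaler = fit_scaler(X, feature_names)
    Xs = scaler.transform(X)
    Xvs = scaler.transform(X_val)
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd == 0.0:
        y_sd = 1.0
    ys = (y - y_mean) / y_sd
    yvs = (y_val - y_mean) / y_sd

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    net = _Net(X.shape[1], cfg, rng)

    best_val = np.inf
    best_state = net.state()
    best_epoch = 0
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = Xs.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for k in range(0, n, cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            losses.append(net.train_batch(Xs[idx], ys[idx], cfg, rng))
        val_loss = float(np.mean((net.forward(Xvs) - yvs) ** 2))
        history["train_loss"].append(float(np.mean(losses)) * y_sd**2)
        history["val_loss"].append(val_loss * y_sd**2)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    net.load_state(best_state)
    return TrainedModel(
        target=target,
        net=net,
        scaler=scaler,
        config=cfg,
        y_mean=y_mean,
        y_sd=y_sd,
        history=history,
    )


def predict_bp(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predict blood pressure (mmHg) for feature rows; dropout disabled."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"model expects {model.n_features}-wide input, got shape {X.shape}"
        )
    out = model.net.forward(model.scaler.transform(X))
    if not np.isfinite(out).all():
        raise ValidationError("model produced non-finite predictions")
    return out * model.y_sd + model.y_mean


# --------------------------------------------------------------------------
# Serialization (versioned JSON: weights + scaler + config)
# --------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "target": model.target,
        "config": {
            "hidden_sizes": list(model.config.hidden_sizes),
            "dropout_rate": model.config.dropout_rate,
            "learning_rate": model.config.learning_rate,
            "max_epochs": model.config.max_epochs,
            "batch_size": model.config.batch_size,
            "early_stop_patience": model.config.early_stop_patience,
            "seed": model.config.seed,
        },
        "scaler": {
            "mean": model.scaler.mean.tolist(),
            "sd": model.scaler.sd.tolist(),
            "feature_names": list(model.scaler.feature_names)
            if model.scaler.feature_names
            else None,
        },
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "weights": [p.tolist() for p in model.net.params()],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != 1:
        raise ValidationError("unsupported model format version")
    cfg = MLPConfig(
        hidden_sizes=tuple(payload["config"]["hidden_sizes"]),
        dropout_rate=payload["config"]["dropout_rate"],
        learning_rate=payload["config"]["learning_rate"],
        max_epochs=payload["config"]["max_epochs"],
        batch_size=payload["config"]["batch_size"],
        early_stop_patience=payload["config"]["early_stop_patience"],
        seed=payload["config"]["seed"],
    )
    weights = [np.asarray(w, dtype=np.float64) for w in payload["weights"]]
    net = _Net(weights[0].shape[0], cfg, np.random.Generator(np.random.PCG64(0)))
    net.load_state(weights)
    names = payload["scaler"]["feature_names"]
    scaler = FeatureScaler(
        mean=np.asarray(payload["scaler"]["mean"]),
        sd=np.asarray(payload["scaler"]["sd"]),
        feature_names=tuple(names) if names else None,
    )
    return TrainedModel(
        target=payload["target"],
        net=net,
        scaler=scaler,
        config=cfg,
        y_mean=payload["y_mean"],
        y_sd=payload["y_sd"],
    )
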