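"""Risk-score regression models and the shared training procedure.

Five families share one input representation (the 26-D normalized skeleton
vector) and one target (the continuous discounted risk label):

* ``mlp``  — 26 -> 256 -> 128 -> 1, ReLU, dropout 0.1 (the primary model);
* ``cnn``  — input reshaped to 2 x 13, two valid length-3 convolutions
  (2 -> 32 -> 64) with ReLU, global average pooling, head 64 -> 64 -> 1;
* ``gcn``  — 13 nodes x 2 features on the fixed anatomical skeleton graph
  (self-loops, symmetric normalization), 2 layers of width 64, head
  832 -> 256 -> 128 -> 64 -> 1;
* ``rf``   — scikit-learn RandomForestRegressor, 300 trees, unlimited depth;
* ``lstm`` — (5, 26) sequences of the first five 30 fps frames, one layer
  of hidden size 64, head on the last hidden state.

Neural families minimize mini-batch MSE with Adam (lr 1e-3, batch 512, at
most 50 epochs) and return the checkpoint with minimum validation MSE.
Inference is deterministic (dropout off); outputs are unclipped real
scores, since clipping would silently alter the MSE against the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .. import humanoid
from ._nn import Adam, CNNNet, GCNNet, LSTMNet, MLPNet, _Net

FAMILIES = ("mlp", "cnn", "gcn", "rf", "lstm")

#: training seeds of the multi-seed protocol (metrics are mean +- std over these)
DEFAULT_SEEDS = (41, 42, 43, 44, 45)


def skeleton_adjacency() -> np.ndarray:
    """Unnormalized 13 x 13 adjacency of the anatomical skeleton graph."""
    A = np.zeros((humanoid.N_KEYPOINTS, humanoid.N_KEYPOINTS))
    for a, b in humanoid.SKELETON_EDGES:
        i, j = humanoid.KEYPOINT_INDEX[a], humanoid.KEYPOINT_INDEX[b]
        A[i, j] = A[j, i] = 1.0
    return A


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus its (fixed) architecture configuration."""

    family: str = "mlp"
    rf_n_estimators: int = 300
    rf_max_depth: int | None = None
    lstm_seq_len: int = 5

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Shared neural training settings."""

    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 50
    val_fraction: float = 0.1
    seeds: tuple[int, ...] = DEFAULT_SEEDS

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")


@dataclass
class TrainedModel:
    """A fitted risk regressor with its training history."""

    family: str
    seed: int
    net: object  # _Net or RandomForestRegressor
    history: list = field(default_factory=list)  # dicts: epoch, train_mse, val_mse
    selected_epoch: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic risk scores; X is (B, 26) or (B, 5, 26) for lstm."""
        X = np.asarray(X, float)
        if self.family == "lstm":
            if X.ndim == 2 and X.shape[1] == 26:
                raise ValueError("lstm expects (B, 5, 26) sequences")
        elif X.ndim != 2 or X.shape[1] != 26:
            raise ValueError(f"{self.family} expects (B, 26) features, got {X.shape}")
        if self.family == "rf":
            return self.net.predict(X)
        return self.net.predict(X)


def build_model(spec: ModelSpec, seed: int):
    """Instantiate an untrained, seeded model for the given family."""
    spec.validate()
    if spec.family == "mlp":
        return MLPNet(seed)
    if spec.family == "cnn":
        return CNNNet(seed)
    if spec.family == "gcn":
        return GCNNet(seed, skeleton_adjacency())
    if spec.family == "lstm":
        return LSTMNet(seed, seq_len=spec.lstm_seq_len)
    return RandomForestRegressor(
        n_estimators=spec.rf_n_estimators, max_depth=spec.rf_max_depth, random_state=seed
    )


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def train(
    model: _Net,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    family: str = "mlp",
) -> TrainedModel:
    """Mini-batch MSE training with Adam; keeps the best-validation checkpoint.

    ``train_set``/``val_set`` are (X, y) pairs.  The model's own seeded
    generator drives shuffling and dropout, so two runs from the same seed
    are bitwise identical.  Raises on non-finite loss.
    """
    config = config or TrainConfig()
    config.validate()
    X_tr, y_tr = (np.asarray(a, float) for a in train_set)
    X_val, y_val = (np.asarray(a, float) for a in val_set)
    opt = Adam(model.params, lr=config.learning_rate)
    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = 0
    history = []
    n = len(X_tr)
    for epoch in range(1, config.max_epochs + 1):
        perm = model.rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            yhat, cache = model.forward(Xb, train=True)
            resid = yhat - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (family={family})"
                )
            grads = model.backward(cache, 2.0 * resid / len(yb))
            opt.update(model.params, grads)
            batch_losses.append(loss)
        val_mse = _mse(model.predict(X_val), y_val)
        history.append(
            {"epoch": epoch, "train_mse": float(np.mean(batch_losses)), "val_mse": val_mse}
        )
        if val_mse < best_val:
            best_val = val_mse
            best_params = model.copy_params()
            best_epoch = epoch
    model.set_params(best_params)
    return TrainedModel(
        family=family, seed=model.seed, net=model, history=history, selected_epoch=best_epoch
    )


def train_rf(
    train_set: tuple[np.ndarray, np.ndarray], seed: int, spec: ModelSpec | None = None
) -> TrainedModel:
    """Fit the 300-tree regression forest on (u, y)."""
    spec = spec or ModelSpec(family="rf")
    rf = build_model(ModelSpec(family="rf", rf_n_estimators=spec.rf_n_estimators), seed)
    X, y = train_set
    rf.fit(np.asarray(X, float), np.asarray(y, float))
    return TrainedModel(family="rf", seed=seed, net=rf)


def build_lstm_sequences(episode_frames: np.ndarray, t_frames: int = 5) -> np.ndarray:
    """Validate/assemble (n, 5, 26) frame sequences for the LSTM.

    ``episode_frames`` come from the episode pipeline, which captures the
    first five 30 fps frames of each rollout and pads episodes that fall
    before frame 4 by repeating the last frame at or before the fall.
    """
    frames = np.asarray(episode_frames, float)
    if frames.ndim != 3 or frames.shape[1] != t_frames or frames.shape[2] != 26:
        raise ValueError(f"expected (n, {t_frames}, 26) frames, got {frames.shape}")
    return frames


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Score inputs with a trained model (shape-checked, deterministic)."""
    return model.predict(X)


def fit_family(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Convenience: build and fit one family with one seed."""
    spec = ModelSpec(family=family)
    if family == "rf":
        return train_rf((X_train, y_train), seed, spec)
    net = build_model(spec, seed)
    return train(net, (X_train, y_train), (X_val, y_val), config, family=family)
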