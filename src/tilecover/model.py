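"""The shallow binary CNN tile classifier: build, train, predict, persist.

The classifier maps a normalized ``tile x tile x 3`` array in [0, 1] to a
probability that the tile shows the target species.  The default
architecture is deliberately shallow — two same-padding conv/pool blocks,
one dense layer, dropout, and a single sigmoid unit — which is adequate
for 30-px tiles whose decisive features are colour and coarse texture.
Training uses Adam on binary cross-entropy with the default
hyperparameters epochs=30, batch=128, dropout=0.2, lr=0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledTileSet
from .errors import ConfigurationError
from .nn import Adam, Network, bce_loss, sigmoid

__all__ = ["TrainConfig", "TileClassifier", "TrainingHistory",
           "DEFAULT_ARCHITECTURE", "build_network", "train", "predict_tiles"]

#: Two conv/pool blocks, a 64-unit dense layer, dropout, one sigmoid unit.
DEFAULT_ARCHITECTURE: list[dict] = [
    {"type": "conv", "filters": 32, "kernel": 3},
    {"type": "maxpool", "size": 2},
    {"type": "conv", "filters": 64, "kernel": 3},
    {"type": "maxpool", "size": 2},
    {"type": "flatten"},
    {"type": "dense", "units": 64, "activation": "relu"},
    {"type": "dropout", "rate": 0.2},
    {"type": "dense", "units": 1, "activation": "linear"},
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the standard recipe)."""

    epochs: int = 30
    batch_size: int = 128
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    decision_threshold: float = 0.5
    seed: int = 0
    steps_per_epoch: int | None = None  # None: ceil(n_train / batch_size)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch train/validation loss and accuracy."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def append(self, epoch, train_loss, train_acc, val_loss, val_acc) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(float(train_loss))
        self.train_acc.append(float(train_acc))
        self.val_loss.append(float(val_loss))
        self.val_acc.append(float(val_acc))

    def __len__(self) -> int:
        return len(self.epochs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss, "train_acc": self.train_acc,
             "val_loss": self.val_loss, "val_acc": self.val_acc}
        )


def _architecture_with_dropout(architecture: Sequence[dict], rate: float) -> list[dict]:
    out = []
    for layer in architecture:
        layer = dict(layer)
        if layer["type"] == "dropout":
            layer["rate"] = rate
        out.append(layer)
    return out


class TileClassifier:
    """Handle around a (possibly trained) tile network.

    Use :func:`build_network` or the constructor to create one, ``fit`` to
    train it, ``predict_proba`` / ``predict`` to apply it, and
    ``save`` / ``load`` to persist it.
    """

    def __init__(self, tile_size: int, config: TrainConfig | None = None,
                 architecture: Sequence[dict] | None = None, _network: Network | None = None):
        self.config = config or TrainConfig()
        self.tile_size = int(tile_size)
        if self.tile_size < 8:
            raise ConfigurationError(f"tile_size must be >= 8, got {tile_size}")
        arch = _architecture_with_dropout(architecture or DEFAULT_ARCHITECTURE,
                                          self.config.dropout_rate)
        n_pools = sum(1 for d in arch if d["type"] == "maxpool")
        if self.tile_size // (2 ** n_pools) < 1:
            raise ConfigurationError(
                f"tile_size {tile_size} too small for {n_pools} pooling stages"
            )
        self.architecture = arch
        self.network = _network or Network.from_descriptor(
            arch, (self.tile_size, self.tile_size, 3), seed=self.config.seed
        )
        self.history = TrainingHistory()

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        train_data: LabeledTileSet | Iterator[tuple[np.ndarray, int]],
        validation_set: LabeledTileSet,
        n_train: int | None = None,
    ) -> "TileClassifier":
        """Train for ``config.epochs`` epochs; returns self with history.

        ``train_data`` is either a LabeledTileSet (tiles are normalized
        internally, order reshuffled every epoch) or an infinite stream of
        single (normalized tile, label) pairs as produced by
        ``augment_stream`` — in that case ``n_train`` (or
        ``config.steps_per_epoch``) sets the epoch length.
        """
        cfg = self.config
        if len(validation_set) == 0:
            raise ConfigurationError("validation set must not be empty")
        xv, yv = validation_set.arrays()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261]))
        optimizer = Adam(self.network.parameters(), learning_rate=cfg.learning_rate)

        from_set = isinstance(train_data, LabeledTileSet)
        if from_set:
            xt, yt = train_data.arrays()
            n = len(yt)
            if n == 0:
                raise ConfigurationError("training set must not be empty")
            steps = cfg.steps_per_epoch or -(-n // cfg.batch_size)
        else:
            if cfg.steps_per_epoch is None and n_train is None:
                raise ConfigurationError("stream training needs steps_per_epoch or n_train")
            steps = cfg.steps_per_epoch or -(-int(n_train) // cfg.batch_size)

        for epoch in range(1, cfg.epochs + 1):
            losses, accs = [], []
            if from_set:
                order = rng.permutation(n)
            for step in range(steps):
                if from_set:
                    idx = order[step * cfg.batch_size : (step + 1) * cfg.batch_size]
                    if len(idx) == 0:
                        continue
                    xb, yb = xt[idx], yt[idx]
                else:
                    pairs = [next(train_data) for _ in range(cfg.batch_size)]
                    xb = np.stack([p[0] for p in pairs])
                    yb = np.array([p[1] for p in pairs], dtype=np.float64)
                logits = self.network.forward_logits(xb, train=True, rng=rng)
                losses.append(bce_loss(logits, yb))
                p = sigmoid(logits).ravel()
                accs.append(float(np.mean((p >= cfg.decision_threshold) == (yb >= 0.5))))
                dlogits = ((p - yb) / len(yb)).reshape(-1, 1).astype(np.float32)
                self.network.backward(dlogits)
                optimizer.step(self.network.gradients())
            val_logits = self.network.forward_logits(xv)
            val_p = sigmoid(val_logits).ravel()
            self.history.append(
                epoch,
                float(np.mean(losses)),
                float(np.mean(accs)),
                bce_loss(val_logits, yv),
                float(np.mean((val_p >= cfg.decision_threshold) == (yv >= 0.5))),
            )
        return self

    # -------------------------------------------------------------- predict
    def predict_proba(self, tiles: np.ndarray) -> np.ndarray:
        """Per-tile probability of the target class.

        ``tiles`` is ``(n, t, t, 3)``, values in [0, 1] (uint8 input is
        rescaled automatically).  An empty input yields an empty result.
        """
        tiles = np.asarray(tiles)
        if tiles.size == 0:
            return np.empty(0)
        if tiles.ndim == 3:
            tiles = tiles[None]
        if tiles.shape[1:] != (self.tile_size, self.tile_size, 3):
            raise ValueError(
                f"expected tiles of shape (n, {self.tile_size}, {self.tile_size}, 3), "
                f"got {tiles.shape}"
            )
        if tiles.dtype == np.uint8:
            tiles = tiles.astype(np.float32) / 255.0
        return self.network.predict_proba(tiles)

    def predict(self, tiles: np.ndarray, threshold: float | None = None) -> np.ndarray:
        """Binary calls at the decision threshold (default 0.5)."""
        thr = self.config.decision_threshold if threshold is None else threshold
        return (self.predict_proba(tiles) >= thr).astype(np.int8)

    # -------------------------------------------------------------- persist
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.network.save(directory / "weights.npz", directory / "architecture.json")
        meta = {"tile_size": self.tile_size, "train_config": asdict(self.config)}
        (directory / "classifier.json").write_text(json.dumps(meta, indent=2))
        self.history.to_frame().to_csv(directory / "history.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TileClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "classifier.json").read_text())
        network = Network.load(directory / "weights.npz", directory / "architecture.json")
        clf = cls(meta["tile_size"], TrainConfig(**meta["train_config"]), _network=network,
                  architecture=network.descriptor())
        hist_path = directory / "history.csv"
        if hist_path.exists():
            frame = pd.read_csv(hist_path)
            for _, row in frame.iterrows():
                clf.history.append(int(row["epoch"]), row["train_loss"], row["train_acc"],
                                   row["val_loss"], row["val_acc"])
        return clf


# Functional aliases matching the pipeline vocabulary.
def build_network(tile_size: int, config: TrainConfig | None = None,
                  architecture: Sequence[dict] | None = None) -> TileClassifier:
    """Create an untrained tile classifier."""
    return TileClassifier(tile_size, config, architecture)


def train(model: TileClassifier, train_data, validation_set: LabeledTileSet,
          n_train: int | None = None) -> TileClassifier:
    """Train ``model`` in place; see :meth:`TileClassifier.fit`."""
    return model.fit(train_data, validation_set, n_train=n_train)


def predict_tiles(model: TileClassifier, tiles: np.ndarray,
                  threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, binary calls) for a batch of tiles."""
    probs = model.predict_proba(tiles)
    thr = model.config.decision_threshold if threshold is None else threshold
    return probs, (probs >= thr).astype(np.int8)
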