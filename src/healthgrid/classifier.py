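"""Small CNN classifying 6x6 health maps into health / sub-health / illness.

The network is a pared-down LeNet-5: two convolution layers with 2x2
kernels (3 filters, then 9), one 2x2 max-pooling stage, a fully connected
hidden layer, and a 3-way softmax output. With same-padding convolutions the
pooled feature map flattens to 9*3*3 = 81 units. Inputs are gray maps scaled
to [0, 1].

The network is implemented directly on numpy arrays — explicit forward pass,
backpropagation, and Adam updates — which keeps training bit-reproducible
for a fixed seed on maps this small. Training minimizes cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .healthmap import MAP_SHAPE, HealthMap

__all__ = [
    "CONV1_FILTERS",
    "CONV2_FILTERS",
    "KERNEL_SIZE",
    "POOL_SIZE",
    "N_CLASSES",
    "LABEL_NAMES",
    "CNNConfig",
    "LabeledDataset",
    "CNNModel",
    "TrainingHistory",
    "build_model",
    "train",
    "predict",
]

# Fixed architecture: 2x2 kernels, 3 then 9 filters, one 2x2 max-pool.
CONV1_FILTERS = 3
CONV2_FILTERS = 9
KERNEL_SIZE = 2
POOL_SIZE = 2
N_CLASSES = 3
LABEL_NAMES = ("health", "sub-health", "illness")

_POOLED_SIDE = MAP_SHAPE[0] // POOL_SIZE                  # 3
_FLAT_UNITS = CONV2_FILTERS * _POOLED_SIDE * _POOLED_SIDE  # 81


@dataclass(frozen=True)
class CNNConfig:
    """Training hyper-parameters; the layer topology itself is fixed."""

    fc_units: int = 32
    activation: str = "relu"   # "relu" or "tanh"
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_units < 1:
            raise ValueError("fc_units must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")

    @property
    def parameter_count(self) -> int:
        k2 = KERNEL_SIZE * KERNEL_SIZE
        conv1 = (k2 * 1 + 1) * CONV1_FILTERS
        conv2 = (k2 * CONV1_FILTERS + 1) * CONV2_FILTERS
        fc = (_FLAT_UNITS + 1) * self.fc_units
        out = (self.fc_units + 1) * N_CLASSES
        return conv1 + conv2 + fc + out


@dataclass
class LabeledDataset:
    """(map, label) pairs with a disjoint, covering train/test partition."""

    maps: np.ndarray          # (N, 6, 6) uint8 gray values
    labels: np.ndarray        # (N,) ints in 0..2
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=int)
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if self.maps.ndim != 3 or self.maps.shape[1:] != MAP_SHAPE:
            raise ValueError(f"maps must be (N, {MAP_SHAPE[0]}, {MAP_SHAPE[1]})")
        if self.labels.shape != (self.maps.shape[0],):
            raise ValueError("labels must match maps in length")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
        combined = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(combined, np.arange(self.maps.shape[0])):
            raise ValueError("train/test partition must be disjoint and covering")

    def __len__(self) -> int:
        return int(self.maps.shape[0])

    def train_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.maps[self.train_idx] / 255.0, self.labels[self.train_idx]

    def test_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.maps[self.test_idx] / 255.0, self.labels[self.test_idx]


@dataclass(frozen=True)
class TrainingHistory:
    loss: tuple[float, ...]      # mean cross-entropy per epoch
    accuracy: tuple[float, ...]  # training accuracy per epoch


# ---------------------------------------------------------------------------
# Layer primitives (2x2 same-padding convolution, 2x2 max-pool)
# ---------------------------------------------------------------------------

def _conv2x2_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (N, C, H, W); w: (F, C, 2, 2); same padding on the bottom/right edge.
    n, _, h, wid = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    out = np.zeros((n, w.shape[0], h, wid))
    for di in range(KERNEL_SIZE):
        for dj in range(KERNEL_SIZE):
            out += np.einsum(
                "nchw,fc->nfhw", xp[:, :, di:di + h, dj:dj + wid], w[:, :, di, dj]
            )
    return out + b[None, :, None, None]


def _conv2x2_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, c, h, wid = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(KERNEL_SIZE):
        for dj in range(KERNEL_SIZE):
            patch = xp[:, :, di:di + h, dj:dj + wid]
            dw[:, :, di, dj] = np.einsum("nfhw,nchw->fc", dout, patch)
            dxp[:, :, di:di + h, dj:dj + wid] += np.einsum(
                "nfhw,fc->nchw", dout, w[:, :, di, dj]
            )
    db = dout.sum(axis=(0, 2, 3))
    return dw, db, dxp[:, :, :h, :wid]


def _maxpool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, wid = x.shape
    tiles = x.reshape(n, c, h // POOL_SIZE, POOL_SIZE, wid // POOL_SIZE, POOL_SIZE)
    out = tiles.max(axis=(3, 5))
    # Gradient routing mask; ties share the gradient equally (deterministic).
    mask = tiles == out[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return out, mask

def _maxpool_backward(mask: np.ndarray, dout: np.ndarray) -> np.ndarray:
    n, c, hp, _, wp, _ = mask.shape
    grad = mask * dout[:, :, :, None, :, None]
    return grad.reshape(n, c, hp * POOL_SIZE, wp * POOL_SIZE)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")


class CNNModel:
    """The pared-down LeNet-5 with explicit numpy forward/backward passes."""

    def __init__(self, config: CNNConfig):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(config.seed)
        k2 = KERNEL_SIZE * KERNEL_SIZE

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "w1": he((CONV1_FILTERS, 1, KERNEL_SIZE, KERNEL_SIZE), k2),
            "b1": np.zeros(CONV1_FILTERS),
            "w2": he((CONV2_FILTERS, CONV1_FILTERS, KERNEL_SIZE, KERNEL_SIZE), k2 * CONV1_FILTERS),
            "b2": np.zeros(CONV2_FILTERS),
            "w3": he((_FLAT_UNITS, config.fc_units), _FLAT_UNITS),
            "b3": np.zeros(config.fc_units),
            "w4": he((config.fc_units, N_CLASSES), config.fc_units),
            "b4": np.zeros(N_CLASSES),
        }

    # -- activations -------------------------------------------------------
    def _act(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0) if self.config.activation == "relu" else np.tanh(x)

    def _act_grad(self, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
        if self.config.activation == "relu":
            return (pre > 0).astype(float)
        return 1.0 - post**2

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        # x: (N, 6, 6) in [0, 1]
        x4 = x[:, None, :, :]
        p = self.params
        z1 = _conv2x2_forward(x4, p["w1"], p["b1"])
        a1 = self._act(z1)
        z2 = _conv2x2_forward(a1, p["w2"], p["b2"])
        a2 = self._act(z2)
        pooled, mask = _maxpool_forward(a2)
        flat = pooled.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = self._act(z3)
        logits = a3 @ p["w4"] + p["b4"]
        probs = _softmax(logits)
        cache = {"x4": x4, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
                 "mask": mask, "flat": flat, "z3": z3, "a3": a3}
        return probs, cache

    def _backward(self, probs: np.ndarray, labels: np.ndarray, cache: dict) -> dict:
        p = self.params
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["w4"] = cache["a3"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * self._act_grad(cache["z3"], cache["a3"])
        grads["w3"] = cache["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dpooled = dflat.reshape(n, CONV2_FILTERS, _POOLED_SIDE, _POOLED_SIDE)
        da2 = _maxpool_backward(cache["mask"], dpooled)
        dz2 = da2 * self._act_grad(cache["z2"], cache["a2"])
        grads["w2"], grads["b2"], da1 = _conv2x2_backward(cache["a1"], p["w2"], dz2)
        dz1 = da1 * self._act_grad(cache["z1"], cache["a1"])
        grads["w1"], grads["b1"], _ = _conv2x2_backward(cache["x4"], p["w1"], dz1)
        return grads

    # -- inference ---------------------------------------------------------
    def predict_proba(self, maps: np.ndarray) -> np.ndarray:
        """Class probabilities for (N, 6, 6) gray maps (0..255 or [0,1])."""
        x = np.asarray(maps, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != MAP_SHAPE:
            raise ValueError(f"maps must be (N, {MAP_SHAPE[0]}, {MAP_SHAPE[1]})")
        if x.max() > 1.0:
            x = x / 255.0
        probs, _ = self._forward(x)
        return probs

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights + config; predictions round-trip bit-exactly."""
        np.savez(
            path,
            config=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            trained=np.array(self.trained),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "CNNModel":
        with np.load(path) as data:
            config = CNNConfig(**json.loads(bytes(data["config"]).decode()))
            model = cls(config)
            model.trained = bool(data["trained"])
            for name in _PARAM_NAMES:
                model.params[name] = data[name]
        return model


def build_model(config: CNNConfig | None = None) -> CNNModel:
    """Construct the network with seed-deterministic initial weights."""
    return CNNModel(config or CNNConfig())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

MIN_TRAIN_MAPS = 30


def train(model: CNNModel, dataset: LabeledDataset, config: CNNConfig | None = None) -> TrainingHistory:
    """Train in place with mini-batch Adam on cross-entropy.

    Requires at least 30 training maps with all three classes present.
    Deterministic for a fixed config seed (shuffling uses a dedicated
    generator derived from it).
    """
    config = config or model.config
    x_train, y_train = dataset.train_arrays()
    n = x_train.shape[0]
    if n < MIN_TRAIN_MAPS:
        raise ValueError(f"need at least {MIN_TRAIN_MAPS} training maps, got {n}")
    present = set(np.unique(y_train).tolist())
    missing = sorted(set(range(N_CLASSES)) - present)
    if missing:
        raise ValueError(f"classes missing from training data: {missing}")

    rng = np.random.default_rng(config.seed + 1)  # shuffling stream
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses: list[float] = []
    accs: list[float] = []

    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, cache = model._forward(xb)
            batch_loss = -np.log(np.clip(probs[np.arange(len(idx)), yb], 1e-12, None))
            epoch_loss += float(batch_loss.sum())
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            grads = model._backward(probs, yb, cache)
            step += 1
            for name, g in grads.items():
                m[name] = beta1 * m[name] + (1 - beta1) * g
                v[name] = beta2 * v[name] + (1 - beta2) * g * g
                m_hat = m[name] / (1 - beta1**step)
                v_hat = v[name] / (1 - beta2**step)
                model.params[name] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        losses.append(epoch_loss / n)
        accs.append(epoch_correct / n)

    model.trained = True
    return TrainingHistory(loss=tuple(losses), accuracy=tuple(accs))


def predict(model: CNNModel, health_map: HealthMap | np.ndarray) -> tuple[np.ndarray, int]:
    """Probabilities and argmax label for one map (ties -> lowest class index)."""
    if not model.trained:
        raise ValueError("model has not been trained")
    grid = health_map.grid if isinstance(health_map, HealthMap) else np.asarray(health_map)
    probs = model.predict_proba(grid[None] if grid.ndim == 2 else grid)[0]
    return probs, int(probs.argmax())
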