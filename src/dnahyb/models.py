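"""Neural yield regressors: CNN, CNN_Lite and a bi-directional LSTM.

The convolutional models consume the one-hot pair image.  The first stage is
a 2-D convolution whose kernel spans the full 4-row nucleobase axis with
width 9, realised as an equivalent 1-D convolution over 8 fused input
channels (4 rows x 2 strands); 1-D convolutions of widths 9, 3, 3 and 1
follow, every convolution trailed by ReLU, batch normalisation and dropout,
and fully-connected layers squash to a single sigmoid output in [0, 1].  The
Lite variant keeps the same stage layout with far fewer filters.

The recurrent model embeds the ``<b> a <s> b <s>`` token stream, stacks
bi-directional LSTM layers, and reads the last layer's hidden states at the
first position (the beginning marker) through a dense layer and a sigmoid.

Training minimises mean squared error against the ground-truth yields at
the dataset's reference temperature, with Adam; the best-validation weights
are retained.  Everything runs on the in-repo numpy autograd engine and is
deterministic for a fixed seed on single-threaded execution.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _autograd as ag
from . import encode
from .dataset import HybridisationDataset

DEFAULT_BATCH_SIZE = 512


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNConfig:
    """Convolutional regressor layout.

    ``channels`` gives the output width of the 2-D stage followed by the
    four 1-D stages; ``dense`` the hidden widths of the fully-connected
    head.  Kernel sizes are fixed by design: one 4x9 full-height 2-D stage,
    then 1-D kernels 9, 3, 3, 1.
    """

    conv2d_kernel: tuple[int, int] = (4, 9)
    conv1d_kernels: tuple[int, ...] = (9, 3, 3, 1)
    channels: tuple[int, ...] = (48, 64, 128, 128, 128)
    dense: tuple[int, ...] = (768, 256)
    dropout_rate: float = 0.2
    n_max: int = encode.N_MAX
    lite: bool = False

    def __post_init__(self) -> None:
        if self.conv2d_kernel != (4, 9):
            raise ValueError("first stage must be a full-height 4x9 convolution")
        if self.conv1d_kernels != (9, 3, 3, 1):
            raise ValueError("1-D stages must use kernels 9, 3, 3, 1 in order")
        if len(self.channels) != 1 + len(self.conv1d_kernels):
            raise ValueError("need one channel width per convolution stage")

    @staticmethod
    def lite_default() -> "CNNConfig":
        # the small model needs less regularisation than the deep CNN
        return CNNConfig(channels=(16, 24, 40, 40, 40), dense=(440, 96),
                         dropout_rate=0.1, lite=True)


@dataclass(frozen=True)
class RNNConfig:
    """Bi-directional LSTM regressor layout (always bidirectional, scalar
    output read from the first-position hidden state)."""

    embedding_dim: int = 32
    hidden_dim: int = 80
    num_layers: int = 2
    dropout_rate: float = 0.2
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not self.bidirectional:
            raise ValueError("the recurrent regressor is always bidirectional")
        if self.num_layers < 1:
            raise ValueError("need at least one recurrent layer")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _flatten_image_batch(images: np.ndarray) -> np.ndarray:
    # (B, 4, W, 2) -> (B, 8, W): strand channel fused into the row axis so
    # the full-height 2-D kernel becomes an equivalent 1-D kernel
    b, h, w, c = images.shape
    return images.transpose(0, 3, 1, 2).reshape(b, c * h, w)


class _CNNNet(ag.Module):
    def __init__(self, config: CNNConfig, rng: np.random.Generator):
        super().__init__()
        kernels = (config.conv2d_kernel[1],) + config.conv1d_kernels
        c_in = 2 * config.conv2d_kernel[0]
        convs, norms, drops = [], [], []
        for c_out, k in zip(config.channels, kernels):
            convs.append(ag.Conv1d(c_in, c_out, k, rng, padding=k // 2))
            norms.append(ag.BatchNorm(c_out))
            drops.append(ag.Dropout(config.dropout_rate, rng))
            c_in = c_out
        self.convs = convs
        self.norms = norms
        self.drops = drops
        width = config.n_max * config.channels[-1]
        dense = []
        for n_out in config.dense:
            dense.append(ag.Linear(width, n_out, rng))
            width = n_out
        self.dense = dense
        self.head_dropout = ag.Dropout(config.dropout_rate, rng)
        self.out = ag.Linear(width, 1, rng)

    def __call__(self, images: np.ndarray) -> ag.Tensor:
        x = ag.Tensor(_flatten_image_batch(images))
        for conv, norm, drop in zip(self.convs, self.norms, self.drops):
            x = drop(norm(conv(x).relu()))
        x = x.reshape(x.shape[0], -1)
        for layer in self.dense:
            x = self.head_dropout(layer(x).relu())
        return self.out(x).sigmoid().reshape(-1)


class _RNNNet(ag.Module):
    def __init__(self, config: RNNConfig, rng: np.random.Generator):
        super().__init__()
        self.embedding = ag.Embedding(len(encode.VOCABULARY),
                                      config.embedding_dim, rng)
        layers = []
        n_in = config.embedding_dim
        for _ in range(config.num_layers):
            layers.append((ag.LSTMLayer(n_in, config.hidden_dim, rng),
                           ag.LSTMLayer(n_in, config.hidden_dim, rng)))
            n_in = 2 * config.hidden_dim
        self.forward_layers = [f for f, _ in layers]
        self.backward_layers = [b for _, b in layers]
        self.drop = ag.Dropout(config.dropout_rate, rng)
        self.out = ag.Linear(2 * config.hidden_dim, 1, rng)

    def __call__(self, tokens: np.ndarray) -> ag.Tensor:
        emb = self.embedding(tokens)
        xs = [emb[:, t, :] for t in range(tokens.shape[1])]
        for i, (fwd, bwd) in enumerate(zip(self.forward_layers,
                                           self.backward_layers)):
            h_fwd = fwd(xs)
            h_bwd = bwd(xs, reverse=True)
            xs = [ag.concat([f, b], axis=1) for f, b in zip(h_fwd, h_bwd)]
            if i < len(self.forward_layers) - 1:
                xs = [self.drop(x) for x in xs]
        return self.out(xs[0]).sigmoid().reshape(-1)


# ---------------------------------------------------------------------------
# Predictor facade
# ---------------------------------------------------------------------------

ARCHITECTURES = ("cnn", "cnn-lite", "rnn")


@dataclass
class TrainedPredictor:
    """A (possibly untrained) yield regressor with its training metadata."""

    architecture: str
    config: CNNConfig | RNNConfig
    net: ag.Module
    n_max: int = encode.N_MAX
    reference_temperature: float = 57.0
    metadata: dict = field(default_factory=dict)

    @property
    def parameter_count(self) -> int:
        return self.net.n_parameters()

    def _encode(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        # hybridisation is symmetric and the dataset stores unordered pairs
        # canonically (lexicographic), so inputs are canonicalised too
        pairs = [(a, b) if a <= b else (b, a) for a, b in pairs]
        if self.architecture in ("cnn", "cnn-lite"):
            return encode.batch_images(pairs, n_max=self.n_max)
        return encode.batch_tokens(pairs)

    def predict(self, pairs: Sequence[tuple[str, str]],
                batch_size: int = DEFAULT_BATCH_SIZE) -> np.ndarray:
        """Predicted yields in [0, 1], order-preserving and batch-invariant."""
        self.net.eval()
        inputs = self._encode(pairs)
        chunks = [self.net(inputs[i:i + batch_size]).data
                  for i in range(0, len(inputs), batch_size)]
        return np.concatenate(chunks) if chunks else np.empty(0)


def build_model(config: CNNConfig | RNNConfig,
                rng_seed: int = 0,
                reference_temperature: float = 57.0) -> TrainedPredictor:
    """Construct an untrained predictor from a configuration."""
    rng = np.random.default_rng(rng_seed)
    if isinstance(config, CNNConfig):
        architecture = "cnn-lite" if config.lite else "cnn"
        net = _CNNNet(config, rng)
        n_max = config.n_max
    elif isinstance(config, RNNConfig):
        architecture = "rnn"
        net = _RNNNet(config, rng)
        n_max = encode.N_MAX
    else:
        raise TypeError(f"unsupported config type {type(config).__name__}")
    predictor = TrainedPredictor(architecture=architecture, config=config,
                                 net=net, n_max=n_max,
                                 reference_temperature=reference_temperature,
                                 metadata={"seed": rng_seed, "epochs": 0,
                                           "loss_curve": []})
    return predictor


def build_named(architecture: str, rng_seed: int = 0) -> TrainedPredictor:
    """Build one of the three default architectures by name."""
    if architecture == "cnn":
        return build_model(CNNConfig(), rng_seed)
    if architecture == "cnn-lite":
        return build_model(CNNConfig.lite_default(), rng_seed)
    if architecture == "rnn":
        return build_model(RNNConfig(), rng_seed)
    raise ValueError(f"unknown architecture {architecture!r}; "
                     f"choose from {ARCHITECTURES}")


def dataset_fingerprint(ds: HybridisationDataset) -> str:
    h = hashlib.sha256()
    for r in ds.records:
        h.update(f"{r.pair_id}\t{r.seq_a}\t{r.seq_b}".encode())
        for t in sorted(r.yields):
            h.update(f"\t{t:g}:{r.yields[t]:.6f}".encode())
    return h.hexdigest()[:16]


def _split_arrays(predictor: TrainedPredictor, ds: HybridisationDataset,
                  split: str) -> tuple[np.ndarray, np.ndarray]:
    sub = ds.subset(split)
    pairs = [(r.seq_a, r.seq_b) for r in sub.records]
    y = sub.yields_at(predictor.reference_temperature).astype(np.float32)
    return predictor._encode(pairs), y


def train(predictor: TrainedPredictor, ds: HybridisationDataset,
          epochs: int = 20, seed: int = 0,
          batch_size: int = DEFAULT_BATCH_SIZE,
          learning_rate: float = 1e-3,
          lr_schedule: str = "cosine",
          verbose: bool = False) -> TrainedPredictor:
    """Fit the predictor to the dataset's train split by MSE on yields.

    Requires ``train`` and ``validation`` splits.  After every epoch the
    validation MSE is measured (eval mode); the weights of the best epoch
    are restored at the end.  The learning rate follows cosine annealing
    from ``learning_rate`` down to 5% of it across the epochs (pass
    ``lr_schedule="constant"`` to disable).  The loss curve, epoch count,
    seed and a dataset fingerprint are recorded in ``predictor.metadata``.
    """
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr schedule {lr_schedule!r}")
    for required in ("train", "validation"):
        if required not in ds.splits or not ds.splits[required]:
            raise ValueError(f"dataset is missing a non-empty {required!r} split")
    predictor.reference_temperature = ds.reference_temperature
    x_train, y_train = _split_arrays(predictor, ds, "train")
    x_val, y_val = _split_arrays(predictor, ds, "validation")

    rng = np.random.default_rng(seed)
    net = predictor.net
    optimiser = ag.Adam(net.parameters(), lr=learning_rate)
    best_val = np.inf
    best_state = net.state_arrays()
    curve: list[dict] = []
    lr_min = 0.05 * learning_rate
    for epoch in range(epochs):
        if lr_schedule == "cosine" and epochs > 1:
            optimiser.lr = lr_min + 0.5 * (learning_rate - lr_min) * (
                1.0 + np.cos(np.pi * epoch / (epochs - 1)))
        net.train()
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            optimiser.zero_grad()
            pred = net(x_train[idx])
            err = pred - ag.Tensor(y_train[idx])
            loss = (err * err).mean()
            loss.backward()
            optimiser.step()
            losses.append(float(loss.data))
        val_mse = _mse_eval(net, x_val, y_val, batch_size)
        curve.append({"epoch": epoch + 1,
                      "train_mse": float(np.mean(losses)),
                      "validation_mse": val_mse})
        if verbose:
            print(f"epoch {epoch + 1}: train {np.mean(losses):.5f} "
                  f"val {val_mse:.5f}", flush=True)
        if val_mse < best_val:
            best_val = val_mse
            best_state = net.state_arrays()
    net.load_state_arrays(best_state)
    net.eval()
    predictor.metadata.update({
        "epochs": epochs,
        "seed": seed,
        "loss_curve": curve,
        "best_validation_mse": float(best_val),
        "dataset_fingerprint": dataset_fingerprint(ds),
        "reference_temperature": ds.reference_temperature,
    })
    return predictor


def predict_yields(predictor: TrainedPredictor,
                   pairs: Sequence[tuple[str, str]],
                   batch_size: int = DEFAULT_BATCH_SIZE) -> np.ndarray:
    """Functional alias for :meth:`TrainedPredictor.predict`."""
    return predictor.predict(pairs, batch_size=batch_size)


def _mse_eval(net: ag.Module, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    net.eval()
    total = 0.0
    for start in range(0, len(x), batch_size):
        pred = net(x[start:start + batch_size]).data
        total += float(((pred - y[start:start + batch_size]) ** 2).sum())
    return total / len(x)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(predictor: TrainedPredictor, directory) -> None:
    """Write weights (npz) plus a JSON sidecar describing the model."""
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "weights.npz"),
             **predictor.net.state_arrays())
    sidecar = {
        "architecture": predictor.architecture,
        "config": asdict(predictor.config),
        "n_max": predictor.n_max,
        "reference_temperature": predictor.reference_temperature,
        "vocabulary": encode.VOCABULARY,
        "parameter_count": predictor.parameter_count,
        "metadata": predictor.metadata,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(directory) -> TrainedPredictor:
    with open(os.path.join(directory, "model.json")) as fh:
        sidecar = json.load(fh)
    cfg = sidecar["config"]
    if sidecar["architecture"] in ("cnn", "cnn-lite"):
        config = CNNConfig(
            conv2d_kernel=tuple(cfg["conv2d_kernel"]),
            conv1d_kernels=tuple(cfg["conv1d_kernels"]),
            channels=tuple(cfg["channels"]), dense=tuple(cfg["dense"]),
            dropout_rate=cfg["dropout_rate"], n_max=cfg["n_max"],
            lite=cfg["lite"])
    else:
        config = RNNConfig(embedding_dim=cfg["embedding_dim"],
                           hidden_dim=cfg["hidden_dim"],
                           num_layers=cfg["num_layers"],
                           dropout_rate=cfg["dropout_rate"])
    predictor = build_model(config, rng_seed=sidecar["metadata"].get("seed", 0),
                            reference_temperature=sidecar["reference_temperature"])
    with np.load(os.path.join(directory, "weights.npz")) as blob:
        predictor.net.load_state_arrays(dict(blob))
    predictor.net.eval()
    predictor.metadata = sidecar["metadata"]
    return predictor


def write_training_log(predictor: TrainedPredictor, path) -> None:
    """Dump the per-epoch loss curve as CSV."""
    import csv
    curve = predictor.metadata.get("loss_curve", [])
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh,
                                fieldnames=["epoch", "train_mse",
                                            "validation_mse"])
        writer.writeheader()
        writer.writerows(curve)
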