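"""Modular heterogeneous ECG classifier.

Four encoder modules, each emitting a 20-dimensional code, are composable
into any non-empty subset (15 combinations):

* ``raw`` — convolutional stack over the (12, 5000) raw signal: five
  Conv(k3, p1)/MaxPool(k3, s3) stages (24, 48, 64, 72, 96 channels), a
  kernel-1 Conv to 2 channels for dimensionality reduction (40-dim flatten
  instead of 1920), then FC 40 -> 20;
* ``raw_entropy`` — FC 156 -> 20, leaky ReLU, FC 20 -> 20 over the raw-signal
  entropy vector;
* ``qrs`` — a shared convolutional beat encoder g: R^{12x100} -> R^24 mapped
  over the variable-length set of QRS segments, aggregated by elementwise
  (adaptive) max and average pooling into 48 dims, then FC 48 -> 20;
* ``qrs_entropy`` — the same max/avg set aggregation over per-beat 156-dim
  entropy vectors (312 dims concatenated), then FC 312 -> 20, leaky ReLU,
  FC 20 -> 20.

The fusion head concatenates the enabled modules' outputs, applies leaky
ReLU and a final FC to the class count; raw scores are returned (softmax
lives in the loss).  Leaky ReLU (slope 0.01) follows every convolution.

The printed beat-encoder table with zero padding on its middle convolutions
would flatten to 22 dims, contradicting the stated 24-dim contract used
downstream (48 = 2 x 24); padding 1 on all kernel-3 convolutions honors the
contract and is the default, with the narrower variant behind a switch.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .nn import (
    Adam,
    Conv1d,
    Flatten,
    Layer,
    LeakyReLU,
    Linear,
    MaxPool1d,
    Param,
    Sequential,
    softmax,
)

MODULE_NAMES = ("raw", "raw_entropy", "qrs", "qrs_entropy")
ENCODER_DIM = 20
QRS_CODE_DIM = 24
ENTROPY_DIM = 156


@dataclasses.dataclass
class ModuleConfig:
    """Which encoder modules are enabled, and global architecture switches."""

    enabled: tuple[str, ...] = ("raw", "qrs", "qrs_entropy")
    n_classes: int = 2
    leaky_slope: float = 0.01
    qrs_padding_as_printed: bool = False  # True -> 22-dim beat code variant
    normalize_leads: bool = False  # optional per-lead z-score (off by default)
    seed: int = 0
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if not self.enabled:
            raise ValueError("at least one module must be enabled")
        unknown = [m for m in self.enabled if m not in MODULE_NAMES]
        if unknown:
            raise ValueError(f"unknown modules: {unknown}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def fusion_width(self) -> int:
        return ENCODER_DIM * len(self.enabled)


def all_module_combinations() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets of the four modules."""
    out = []
    for mask in range(1, 16):
        out.append(tuple(m for i, m in enumerate(MODULE_NAMES) if mask >> i & 1))
    return out


@dataclasses.dataclass
class SetAggregate:
    """Elementwise max/avg over a set of equal-length vectors."""

    z_max: np.ndarray
    z_avg: np.ndarray

    @property
    def z_all(self) -> np.ndarray:
        return np.concatenate([self.z_max, self.z_avg], axis=-1)


def aggregate_set(encodings: np.ndarray | Sequence[np.ndarray]) -> SetAggregate:
    """Adaptive max + average pooling over a non-empty set of vectors."""
    arr = np.asarray(encodings, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValueError("cannot aggregate an empty set")
    return SetAggregate(arr.max(axis=0), arr.mean(axis=0))


# ---------------------------------------------------------------------------
# architecture builders


def build_raw_encoder(rng, slope=0.01, dtype=np.float32) -> Sequential:
    """Raw-signal encoder; length trace 5000 -> 1666 -> 555 -> 185 -> 61 -> 20."""
    chans = [12, 24, 48, 64, 72, 96]
    layers: list[Layer] = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        layers += [Conv1d(cin, cout, 3, padding=1, rng=rng, slope=slope, dtype=dtype),
                   LeakyReLU(slope), MaxPool1d(3)]
    layers += [Conv1d(96, 2, 1, padding=0, rng=rng, slope=slope, dtype=dtype),
               LeakyReLU(slope), Flatten(),
               Linear(40, ENCODER_DIM, rng=rng, slope=slope, dtype=dtype)]
    return Sequential(layers)


def build_qrs_single_encoder(rng, slope=0.01, as_printed=False,
                             dtype=np.float32) -> Sequential:
    """Beat encoder g over one (12, 100) segment; flattens to 24 (or 22)."""
    p = 0 if as_printed else 1
    layers: list[Layer] = [
        Conv1d(12, 24, 3, padding=1, rng=rng, slope=slope, dtype=dtype),
        LeakyReLU(slope), MaxPool1d(2),
        Conv1d(24, 48, 3, padding=p, rng=rng, slope=slope, dtype=dtype),
        LeakyReLU(slope), MaxPool1d(2),
        Conv1d(48, 96, 3, padding=p, rng=rng, slope=slope, dtype=dtype),
        LeakyReLU(slope), MaxPool1d(2),
        Conv1d(96, 2, 1, padding=0, rng=rng, slope=slope, dtype=dtype),
        LeakyReLU(slope), Flatten(),
    ]
    return Sequential(layers)


def build_entropy_encoder(in_dim, rng, slope=0.01, dtype=np.float32) -> Sequential:
    return Sequential([
        Linear(in_dim, ENCODER_DIM, rng=rng, slope=slope, dtype=dtype),
        LeakyReLU(slope),
        Linear(ENCODER_DIM, ENCODER_DIM, rng=rng, slope=slope, dtype=dtype),
    ])


class _SetPool(Layer):
    """Max+avg pooling over the set axis: (N, S, D) -> (N, 2D)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, s, d = x.shape
        arg = x.argmax(axis=1)
        zmax = np.take_along_axis(x, arg[:, None, :], axis=1)[:, 0, :]
        zavg = x.mean(axis=1)
        self._cache = (arg, (n, s, d))
        return np.concatenate([zmax, zavg], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, (n, s, d) = self._cache
        gmax, gavg = grad[:, :d], grad[:, d:]
        dx = np.broadcast_to(gavg[:, None, :] / s, (n, s, d)).copy()
        np.put_along_axis(dx, arg[:, None, :],
                          np.take_along_axis(dx, arg[:, None, :], axis=1) + gmax[:, None, :],
                          axis=1)
        return dx


class QrsSetEncoder:
    """Map the beat encoder over a set of beats, pool, project to 20 dims.

    Input (N, S, 12, 100): batches are homogeneous in beat count S, so the
    set dimension folds into the batch for the shared convolutional encoder.
    Output is invariant under permutation and duplication of the beat set.
    """

    def __init__(self, rng, slope=0.01, as_printed=False, dtype=np.float32):
        self.single = build_qrs_single_encoder(rng, slope, as_printed, dtype)
        code_dim = 22 if as_printed else QRS_CODE_DIM
        self.pool = _SetPool()
        self.head = Linear(2 * code_dim, ENCODER_DIM, rng=rng, slope=slope, dtype=dtype)
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, s, c, length = x.shape
        if s == 0:
            raise ValueError("record has zero QRS segments")
        self._shape = (n, s)
        codes = self.single.forward(x.reshape(n * s, c, length))
        pooled = self.pool.forward(codes.reshape(n, s, -1))
        return self.head.forward(pooled)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, s = self._shape
        g = self.pool.backward(self.head.backward(grad))
        g = self.single.backward(g.reshape(n * s, -1))
        return g.reshape(n, s, *g.shape[1:])

    def parameters(self) -> list[Param]:
        return self.single.parameters() + self.head.parameters()


class QrsEntropySetEncoder:
    """Pool per-beat entropy vectors (N, S, 156) -> 312, then the shallow head."""

    def __init__(self, rng, slope=0.01, dtype=np.float32):
        self.pool = _SetPool()
        self.head = build_entropy_encoder(2 * ENTROPY_DIM, rng, slope, dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 0:
            raise ValueError("record has zero QRS segments")
        return self.head.forward(self.pool.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.pool.backward(self.head.backward(grad))

    def parameters(self) -> list[Param]:
        return self.head.parameters()


class FusionModel:
    """Composable classifier over any subset of the four encoder modules."""

    def __init__(self, config: ModuleConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        slope, dtype = config.leaky_slope, config.dtype
        self.encoders: dict[str, object] = {}
        if "raw" in config.enabled:
            self.encoders["raw"] = build_raw_encoder(rng, slope, dtype)
        if "raw_entropy" in config.enabled:
            self.encoders["raw_entropy"] = build_entropy_encoder(
                ENTROPY_DIM, rng, slope, dtype)
        if "qrs" in config.enabled:
            self.encoders["qrs"] = QrsSetEncoder(
                rng, slope, config.qrs_padding_as_printed, dtype)
        if "qrs_entropy" in config.enabled:
            self.encoders["qrs_entropy"] = QrsEntropySetEncoder(rng, slope, dtype)
        self.fusion_act = LeakyReLU(slope)
        self.fusion_fc = Linear(config.fusion_width, config.n_classes,
                                rng=rng, slope=slope, dtype=dtype)

    def forward(self, batch: Mapping[str, np.ndarray]) -> np.ndarray:
        """Class scores (N, n_classes) from per-module inputs.

        ``batch`` must hold an entry for every enabled module: ``raw``
        (N, 12, 5000), ``raw_entropy`` (N, 156), ``qrs`` (N, S, 12, 100),
        ``qrs_entropy`` (N, S, 156).
        """
        outs = []
        for name in self.config.enabled:
            if name not in batch:
                raise KeyError(f"batch missing input for enabled module {name!r}")
            x = np.asarray(batch[name], dtype=self.config.dtype)
            if name == "raw" and self.config.normalize_leads:
                mu = x.mean(axis=2, keepdims=True)
                sd = x.std(axis=2, keepdims=True)
                x = (x - mu) / np.maximum(sd, 1e-8)
            outs.append(self.encoders[name].forward(x))
        fused = np.concatenate(outs, axis=1)
        return self.fusion_fc.forward(self.fusion_act.forward(fused))

    def backward(self, dscores: np.ndarray) -> None:
        g = self.fusion_act.backward(self.fusion_fc.backward(dscores))
        offset = 0
        for name in self.config.enabled:
            self.encoders[name].backward(g[:, offset : offset + ENCODER_DIM])
            offset += ENCODER_DIM

    def predict(self, batch: Mapping[str, np.ndarray]) -> np.ndarray:
        return np.argmax(self.forward(batch), axis=1)

    def predict_proba(self, batch: Mapping[str, np.ndarray]) -> np.ndarray:
        return softmax(self.forward(batch).astype(np.float64))

    def parameters(self) -> list[Param]:
        params = []
        for name in self.config.enabled:
            params += self.encoders[name].parameters()
        return params + self.fusion_fc.parameters()

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s

    def save(self, path: str) -> None:
        """Write weights (.npz) plus a JSON manifest alongside."""
        import json

        np.savez(path, *[p.data for p in self.parameters()])
        manifest = {
            "modules": list(self.config.enabled),
            "n_classes": self.config.n_classes,
            "seed": self.config.seed,
            "n_parameters": int(sum(p.data.size for p in self.parameters())),
        }
        with open(path + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path: str, config: ModuleConfig) -> "FusionModel":
        model = cls(config)
        with np.load(path if path.endswith(".npz") else path + ".npz") as data:
            model.load_state([data[k] for k in data.files])
        return model


# ---------------------------------------------------------------------------
# architecture arithmetic


def count_weights(layer: Layer | tuple[int, int] | tuple[int, int, int]) -> int:
    """Weight count of a layer, excluding biases.

    Accepts a built ``Conv1d``/``Linear`` layer, an ``(in, out)`` tuple for a
    fully-connected layer, or ``(in, out, kernel)`` for a convolution.
    """
    if isinstance(layer, Conv1d):
        return int(layer.weight.data.size)
    if isinstance(layer, Linear):
        return int(layer.weight.data.size)
    if isinstance(layer, tuple):
        if len(layer) == 2:
            return layer[0] * layer[1]
        if len(layer) == 3:
            return layer[0] * layer[1] * layer[2]
    raise TypeError(f"cannot count weights of {layer!r}")


def shape_trace(encoder: Sequential, input_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """(channels, length) after every layer of a convolutional encoder.

    Flatten and Linear layers are reported as (1, width).
    """
    c, length = input_shape
    trace = []
    for layer in encoder.layers:
        if isinstance(layer, Conv1d):
            c, length = layer.out_channels, layer.out_length(length)
        elif isinstance(layer, MaxPool1d):
            length = layer.out_length(length)
        elif isinstance(layer, Flatten):
            c, length = 1, c * length
        elif isinstance(layer, Linear):
            c, length = 1, layer.out_features
        trace.append((c, length))
    return trace
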