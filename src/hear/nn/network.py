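"""The hierarchical ensemble network: spec, wiring, and parameter counts.

Layer 1 extracts per-channel temporal features: each of the S x C sensor
channels runs its own sequence-returning LSTM followed by a 1-D
convolution, ReLU, batch norm and temporal max-pool; the 9 channels of a
sensor are then concatenated into a 2-D map. Layer 2 fuses: a per-sensor
2-D convolution block, cross-sensor concatenation along feature maps, and
a second 2-D convolution block. A dense regression head with softmax
produces class probabilities.

Under the defaults (post-wavelet length 28, 2 sensors, 9 channels,
LSTM 32, conv1d 8@5, conv2d 8@3x3 then 32@3x3, head 64-32-16-8, M = 7)
the stage shapes are 28 -> 14 -> 14x72 -> 7x36x8 -> 7x36x16 -> 4x18x32
-> 2304 and the per-layer parameter counts are 4352 (LSTM), 1288
(1D conv), 80 and 4640 (2-D convs) and 147,520 (first dense).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    GroupedConv1D,
    GroupedLSTM,
    MaxPool1D,
    MaxPool2D,
    ReLU,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative architecture description; fully determines the model.

    ``t_in`` is the post-wavelet window length (50-sample windows shrink
    to 28 under the default one-level 8-tap decomposition).
    """

    t_in: int = 28
    n_sensors: int = 2
    n_channels: int = 9
    lstm_units: int = 32
    conv1d_filters: int = 8
    conv1d_kernel: int = 5
    pool1d: int = 2
    conv2d_sensor_filters: int = 8
    conv2d_fused_filters: int = 32
    conv2d_kernel: tuple[int, int] = (3, 3)
    pool2d: tuple[int, int] = (2, 2)
    head: tuple[int, ...] = (64, 32, 16, 8)
    n_classes: int = 7
    dropout: float = 0.5
    lstm_in_dim: int = 1  # univariate per-channel input

    def __post_init__(self) -> None:
        for name in ("t_in", "n_sensors", "n_channels", "lstm_units",
                     "conv1d_filters", "conv1d_kernel",
                     "conv2d_sensor_filters", "conv2d_fused_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.t_in % self.pool1d != 0:
            raise ValueError(
                f"stage Max-pooling1D: length {self.t_in} not divisible by "
                f"{self.pool1d} (floor mode requires exact division)"
            )
        h1 = self.t_in // self.pool1d
        w1 = self.n_channels * self.conv1d_filters
        if h1 % self.pool2d[0] != 0 or w1 % self.pool2d[1] != 0:
            raise ValueError(
                f"stage Max-pooling2D (per-sensor): map {h1}x{w1} not "
                f"divisible by pool {self.pool2d} (floor mode)"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def n_groups(self) -> int:
        return self.n_sensors * self.n_channels

    @property
    def pooled_t(self) -> int:
        return self.t_in // self.pool1d

    @property
    def sensor_map(self) -> tuple[int, int]:
        """(height, width) of the per-sensor 2-D map after channel fusion."""
        return (self.pooled_t, self.n_channels * self.conv1d_filters)

    @property
    def sensor_pooled(self) -> tuple[int, int]:
        h, w = self.sensor_map
        return (h // self.pool2d[0], w // self.pool2d[1])

    @property
    def fused_pooled(self) -> tuple[int, int]:
        # the final pooling runs in ceil mode (7 -> 4)
        h, w = self.sensor_pooled
        return (-(-h // self.pool2d[0]), -(-w // self.pool2d[1]))

    @property
    def flat_dim(self) -> int:
        h, w = self.fused_pooled
        return h * w * self.conv2d_fused_filters

    def shape_chain(self) -> list[tuple[str, tuple]]:
        """(stage, (feature maps, map size)) per stage, mirroring the
        construction tables."""
        h1, w1 = self.sensor_map
        hs, ws = self.sensor_pooled
        hf, wf = self.fused_pooled
        chain = [
            ("LSTM", (self.lstm_units, self.t_in)),
            ("1D-CNN", (self.conv1d_filters, self.t_in)),
            ("BN-1", (self.conv1d_filters, self.t_in)),
            ("Max-pooling1D", (self.conv1d_filters, self.pooled_t)),
            ("Concatenate-channels", (w1, self.pooled_t)),
            ("Reshape", (1, (h1, w1))),
            ("2D-CNN-sensor", (self.conv2d_sensor_filters, (h1, w1))),
            ("BN-2", (self.conv2d_sensor_filters, (h1, w1))),
            ("Max-pooling2D-sensor", (self.conv2d_sensor_filters, (hs, ws))),
            ("Concatenate-sensors",
             (self.n_sensors * self.conv2d_sensor_filters, (hs, ws))),
            ("2D-CNN-fused", (self.conv2d_fused_filters, (hs, ws))),
            ("BN-3", (self.conv2d_fused_filters, (hs, ws))),
            ("Max-pooling2D-fused", (self.conv2d_fused_filters, (hf, wf))),
            ("Flatten", (1, self.flat_dim)),
        ]
        for k, width in enumerate(self.head, start=1):
            chain.append((f"Dense-{k}", (1, width)))
        chain.append((f"Dense-{len(self.head) + 1}", (1, self.n_classes)))
        return chain

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        for key in ("conv2d_kernel", "pool2d", "head"):
            d[key] = tuple(d[key])
        return cls(**d)


def count_parameters(spec: NetworkSpec, layer: str = "all") -> int:
    """Analytic parameter count per layer instance (or the whole model).

    Conventions: LSTM = 4(H(D + H) + H); conv = filters x (kernel volume
    x input maps + 1); batch norm = 4 x maps (scale, shift and the two
    running statistics, the bookkeeping convention of the construction
    tables); dense = in x out + out. Per-layer names count one instance
    (one channel's LSTM, one sensor's conv); "all" multiplies out the
    S x C channel copies and S sensor branches.
    """
    H, D = spec.lstm_units, spec.lstm_in_dim
    kh, kw = spec.conv2d_kernel
    dense_widths = (spec.flat_dim,) + spec.head + (spec.n_classes,)
    counts = {
        "lstm": 4 * (H * (D + H) + H),
        "conv1d": spec.conv1d_filters * (spec.conv1d_kernel * H + 1),
        "bn1": 4 * spec.conv1d_filters,
        "conv2d_sensor": spec.conv2d_sensor_filters * (kh * kw * 1 + 1),
        "bn2": 4 * spec.conv2d_sensor_filters,
        "conv2d_fused": spec.conv2d_fused_filters
        * (kh * kw * spec.n_sensors * spec.conv2d_sensor_filters + 1),
        "bn3": 4 * spec.conv2d_fused_filters,
    }
    for k in range(len(dense_widths) - 1):
        counts[f"dense{k + 1}"] = (
            dense_widths[k] * dense_widths[k + 1] + dense_widths[k + 1]
        )
    if layer == "all":
        per_channel = counts["lstm"] + counts["conv1d"] + counts["bn1"]
        per_sensor = counts["conv2d_sensor"] + counts["bn2"]
        dense_total = sum(v for k, v in counts.items() if k.startswith("dense"))
        return (
            spec.n_groups * per_channel
            + spec.n_sensors * per_sensor
            + counts["conv2d_fused"]
            + counts["bn3"]
            + dense_total
        )
    if layer not in counts:
        raise ValueError(
            f"unknown layer {layer!r}; expected one of {sorted(counts)} or 'all'"
        )
    return counts[layer]


class HierarchicalNetwork:
    """Trainable model built from a :class:`NetworkSpec`.

    ``forward`` maps a batch ``(B, t_in, S, C)`` to class probabilities
    ``(B, M)`` (softmax rows). Training code uses ``forward_logits`` /
    ``backward`` and the optimizer updates ``parameters()`` in place.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> None:
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        G, H = spec.n_groups, spec.lstm_units
        self.lstm = GroupedLSTM(G, spec.lstm_in_dim, H, rng, dtype)
        self.conv1 = GroupedConv1D(G, H, spec.conv1d_filters,
                                   spec.conv1d_kernel, rng, dtype)
        self.relu1 = ReLU()
        self.bn1 = BatchNorm((G, spec.conv1d_filters), axes=(0, 1), dtype=dtype)
        self.pool1 = MaxPool1D(spec.pool1d)
        self.conv2a = [
            Conv2D(1, spec.conv2d_sensor_filters, spec.conv2d_kernel, rng, dtype)
            for _ in range(spec.n_sensors)
        ]
        self.relu2a = [ReLU() for _ in range(spec.n_sensors)]
        self.bn2a = [
            BatchNorm((spec.conv2d_sensor_filters,), axes=(0, 1, 2), dtype=dtype)
            for _ in range(spec.n_sensors)
        ]
        self.pool2a = [MaxPool2D(spec.pool2d) for _ in range(spec.n_sensors)]
        self.conv2b = Conv2D(
            spec.n_sensors * spec.conv2d_sensor_filters,
            spec.conv2d_fused_filters, spec.conv2d_kernel, rng, dtype)
        self.relu2b = ReLU()
        self.bn2b = BatchNorm((spec.conv2d_fused_filters,), axes=(0, 1, 2),
                              dtype=dtype)
        self.pool2b = MaxPool2D(spec.pool2d, ceil_mode=True)
        widths = (spec.flat_dim,) + spec.head + (spec.n_classes,)
        self.dense = [
            Dense(widths[k], widths[k + 1], rng, dtype)
            for k in range(len(widths) - 1)
        ]
        self.relu_dense = [ReLU() for _ in range(len(spec.head))]
        self.dropout = Dropout(spec.dropout, self._dropout_rng)
        # dropout sits after the second-to-last hidden width (16 under defaults)
        self._dropout_after = max(len(spec.head) - 2, 0)

    # -- bookkeeping --------------------------------------------------------

    def named_layers(self):
        yield "lstm", self.lstm
        yield "conv1d", self.conv1
        yield "bn1", self.bn1
        for s, (c, b) in enumerate(zip(self.conv2a, self.bn2a), start=1):
            yield f"conv2d_sensor/{s}", c
            yield f"bn2/{s}", b
        yield "conv2d_fused", self.conv2b
        yield "bn3", self.bn2b
        for k, d in enumerate(self.dense, start=1):
            yield f"dense{k}", d

    def parameters(self):
        """Yield (name, param array, grad array) for every trainable array."""
        for lname, layer in self.named_layers():
            for pname in layer.params:
                yield f"{lname}/{pname}", layer.params[pname], layer.grads[pname]

    def zero_grad(self) -> None:
        for _, layer in self.named_layers():
            layer.zero_grad()

    def param_count(self, layer: str = "all", include_buffers: bool = True) -> int:
        """Enumerate the built model's arrays (cross-check of
        :func:`count_parameters`). Per-layer names count one instance."""
        table = {
            "lstm": self.lstm,
            "conv1d": self.conv1,
            "bn1": self.bn1,
            "conv2d_sensor": self.conv2a[0],
            "bn2": self.bn2a[0],
            "conv2d_fused": self.conv2b,
            "bn3": self.bn2b,
        }
        for k, d in enumerate(self.dense, start=1):
            table[f"dense{k}"] = d
        if layer == "all":
            return sum(
                lyr.param_count(include_buffers)
                for _, lyr in self.named_layers()
            )
        if layer not in table:
            raise ValueError(f"unknown layer {layer!r}")
        n = table[layer].param_count(include_buffers)
        if layer in ("lstm", "conv1d", "bn1"):
            n //= self.spec.n_groups  # grouped layers store all copies at once
        return n

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        spec = self.spec
        B = X.shape[0]
        expected = (spec.t_in, spec.n_sensors, spec.n_channels)
        if X.shape[1:] != expected:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match spec "
                f"(t_in, S, C) = {expected}"
            )
        X = X.astype(self.dtype, copy=False)
        G, C = spec.n_groups, spec.n_channels
        # (B, T, S, C) -> (B, T, G, 1), group index g = s * C + c
        x = X.reshape(B, spec.t_in, G)[..., None]
        h = self.lstm.forward(x, training)
        h = self.conv1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.bn1.forward(h, training)
        h = self.pool1.forward(h, training)  # (B, T/2, G, F1)
        maps = []
        for s in range(spec.n_sensors):
            m = h[:, :, s * C:(s + 1) * C, :]
            m = np.ascontiguousarray(m).reshape(B, spec.pooled_t, -1)[..., None]
            m = self.conv2a[s].forward(m, training)
            m = self.relu2a[s].forward(m, training)
            m = self.bn2a[s].forward(m, training)
            m = self.pool2a[s].forward(m, training)
            maps.append(m)
        z = np.concatenate(maps, axis=-1)
        z = self.conv2b.forward(z, training)
        z = self.relu2b.forward(z, training)
        z = self.bn2b.forward(z, training)
        z = self.pool2b.forward(z, training)
        z = z.reshape(B, -1)
        for k, dense in enumerate(self.dense[:-1]):
            z = dense.forward(z, training)
            z = self.relu_dense[k].forward(z, training)
            if k == self._dropout_after:
                z = self.dropout.forward(z, training)
        return self.dense[-1].forward(z, training)

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities (softmax over logits)."""
        return softmax(self.forward_logits(X, training))

    def backward(self, dlogits: np.ndarray) -> None:
        spec = self.spec
        B = dlogits.shape[0]
        C = spec.n_channels
        dz = self.dense[-1].backward(dlogits)
        for k in range(len(self.dense) - 2, -1, -1):
            if k == self._dropout_after:
                dz = self.dropout.backward(dz)
            dz = self.relu_dense[k].backward(dz)
            dz = self.dense[k].backward(dz)
        hf, wf = spec.fused_pooled
        dz = dz.reshape(B, hf, wf, spec.conv2d_fused_filters)
        dz = self.pool2b.backward(dz)
        dz = self.bn2b.backward(dz)
        dz = self.relu2b.backward(dz)
        dz = self.conv2b.backward(dz)
        F2a = spec.conv2d_sensor_filters
        dh = np.empty(
            (B, spec.pooled_t, spec.n_groups, spec.conv1d_filters),
            dtype=dz.dtype)
        for s in range(spec.n_sensors):
            dm = dz[..., s * F2a:(s + 1) * F2a]
            dm = self.pool2a[s].backward(dm)
            dm = self.bn2a[s].backward(dm)
            dm = self.relu2a[s].backward(dm)
            dm = self.conv2a[s].backward(dm)
            dh[:, :, s * C:(s + 1) * C, :] = dm[..., 0].reshape(
                B, spec.pooled_t, C, spec.conv1d_filters)
        dh = self.pool1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.conv1.backward(dh)
        self.lstm.backward(dh)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: all arrays plus the spec as JSON."""
        arrays = {}
        for lname, layer in self.named_layers():
            for pname, arr in {**layer.params, **layer.buffers}.items():
                arrays[f"{lname}/{pname}".replace("/", "__")] = arr
        np.savez_compressed(path, __spec__=np.asarray(self.spec.to_json()),
                            **arrays)

    @classmethod
    def load(cls, path, dtype=np.float32) -> "HierarchicalNetwork":
        with np.load(path, allow_pickle=False) as z:
            spec = NetworkSpec.from_json(str(z["__spec__"]))
            model = cls(spec, seed=0, dtype=dtype)
            for lname, layer in model.named_layers():
                for store in (layer.params, layer.buffers):
                    for pname in store:
                        key = f"{lname}/{pname}".replace("/", "__")
                        store[pname][...] = z[key].astype(dtype)
        return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(spec: NetworkSpec, seed: int = 0,
                dtype=np.float32) -> HierarchicalNetwork:
    """Construct a freshly initialized model from a spec (seeded)."""
    return HierarchicalNetwork(spec, seed=seed, dtype=dtype)
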