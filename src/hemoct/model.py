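"""The 3D convolutional network and its exact shape arithmetic.

The classifier is a short stack of same-padded 3D convolutions with ReLU,
non-overlapping ceiling-mode max pooling, and a fully connected head. The
default architecture on a 50 x 50 x 28 input is::

    Conv(3^3, 32) -> Pool(2^3) -> Conv(3^3, 64) -> Pool(2^3)
    -> Conv(3^3, 128) -> Pool(2^3) -> Flatten(25088) -> Dense(1024)
    -> Dropout(0.2) -> Dense(n_classes)

Pooling is ceiling-mode: a trailing incomplete window still emits an output,
so the spatial chain on 50/25/13 is 25 -> 13 -> 7 (floor mode would give 12
and 6 and a different flattened width). Convolutions are the mathematical
convolution (kernel reflected before the sliding inner product); for learned
kernels this is equivalent to cross-correlation up to a relabelling of the
weights. Everything is implemented on numpy arrays, channels last,
batch first: ``(N, W, L, D, C)``. Forward and backward passes are exact
(no autodiff); gradients are used by the Adam loop in :mod:`hemoct.training`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3D",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "Dropout",
    "ArchitectureSpec",
    "table2_spec",
    "layer_output_shapes",
    "count_parameters",
    "conv3d_forward",
    "Network",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Architecture description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conv3D:
    filters: int
    kernel: tuple[int, int, int] = (3, 3, 3)
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValueError("filters must be positive")
        if self.stride != 1:
            raise ValueError("only stride-1 convolutions are supported")
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")
        if any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ValueError(f"kernel dims must be odd and positive, got {self.kernel}")


@dataclass(frozen=True)
class MaxPool3D:
    kernel: tuple[int, int, int] = (2, 2, 2)
    stride: int = 2
    ceil_mode: bool = True

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.kernel):
            raise ValueError("pool kernel dims must be positive")
        if tuple(self.kernel) != (self.stride,) * 3:
            raise ValueError("pooling supports kernel == stride (non-overlapping) only")


@dataclass(frozen=True)
class Flatten:
    pass


@dataclass(frozen=True)
class Dense:
    units: int

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be positive")


@dataclass(frozen=True)
class Dropout:
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


LayerSpec = Union[Conv3D, MaxPool3D, Flatten, Dense, Dropout]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer records plus the activation and class count."""

    layers: tuple[LayerSpec, ...]
    activation: str = "relu"
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.activation not in ("relu",):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.layers or not isinstance(self.layers[0], Conv3D):
            raise ValueError("first layer must be Conv3D")
        dense = [l for l in self.layers if isinstance(l, Dense)]
        if not dense or dense[-1].units != self.n_classes:
            raise ValueError("last Dense layer must have units == n_classes")

    def to_dict(self) -> dict:
        recs = []
        for l in self.layers:
            rec = {"type": type(l).__name__}
            rec.update({k: getattr(l, k) for k in getattr(l, "__dataclass_fields__", {})})
            recs.append(rec)
        return {"layers": recs, "activation": self.activation, "n_classes": self.n_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        kinds = {c.__name__: c for c in (Conv3D, MaxPool3D, Flatten, Dense, Dropout)}
        layers = []
        for rec in d["layers"]:
            rec = dict(rec)
            kind = kinds[rec.pop("type")]
            for key in ("kernel",):
                if key in rec:
                    rec[key] = tuple(rec[key])
            layers.append(kind(**rec))
        return cls(tuple(layers), activation=d["activation"], n_classes=int(d["n_classes"]))


def table2_spec(
    n_classes: int = 2,
    filters: Sequence[int] = (32, 64, 128),
    dense_units: int = 1024,
    dropout: float = 0.2,
    conv_kernel: tuple[int, int, int] = (3, 3, 3),
    pool_kernel: tuple[int, int, int] = (2, 2, 2),
) -> ArchitectureSpec:
    """The default architecture; reduced variants change only the widths."""
    layers: list[LayerSpec] = []
    for f in filters:
        layers.append(Conv3D(filters=int(f), kernel=conv_kernel))
        layers.append(MaxPool3D(kernel=pool_kernel, stride=pool_kernel[0]))
    layers += [Flatten(), Dense(dense_units)]
    if dropout > 0:
        layers.append(Dropout(dropout))
    layers.append(Dense(n_classes))
    return ArchitectureSpec(tuple(layers), n_classes=n_classes)


def layer_output_shapes(
    spec: ArchitectureSpec, input_shape: Sequence[int]
) -> list[Union[tuple[int, int, int, int], int]]:
    """Output size of every shape-changing layer for the given input.

    Conv layers report ``(width, length, depth, filters)``; pooling halves each
    spatial dim with ceiling rounding; Flatten and Dense report widths as
    integers. Dropout is shape-transparent and emits no entry.
    """
    w, l, d = (int(s) for s in input_shape)
    if min(w, l, d) < 1:
        raise ValueError("input_shape entries must be >= 1")
    channels = 1
    shapes: list[Union[tuple[int, int, int, int], int]] = []
    flat: Optional[int] = None
    for layer in spec.layers:
        if isinstance(layer, Conv3D):
            channels = layer.filters
            shapes.append((w, l, d, channels))
        elif isinstance(layer, MaxPool3D):
            s = layer.stride
            if layer.ceil_mode:
                w, l, d = (-(-w // s), -(-l // s), -(-d // s))
            else:
                w, l, d = (w // s, l // s, d // s)
            shapes.append((w, l, d, channels))
        elif isinstance(layer, Flatten):
            flat = w * l * d * channels
            shapes.append(flat)
        elif isinstance(layer, Dense):
            flat = layer.units
            shapes.append(flat)
        # Dropout: shape-transparent
    return shapes


def count_parameters(spec: ArchitectureSpec, input_shape: Sequence[int]) -> int:
    """Total kernel + bias parameter count implied by the shape arithmetic."""
    total = 0
    channels = 1
    w, l, d = (int(s) for s in input_shape)
    flat = None
    for layer in spec.layers:
        if isinstance(layer, Conv3D):
            k1, k2, k3 = layer.kernel
            total += k1 * k2 * k3 * channels * layer.filters + layer.filters
            channels = layer.filters
        elif isinstance(layer, MaxPool3D):
            s = layer.stride
            w, l, d = (-(-w // s), -(-l // s), -(-d // s))
        elif isinstance(layer, Flatten):
            flat = w * l * d * channels
        elif isinstance(layer, Dense):
            assert flat is not None, "Dense requires a preceding Flatten"
            total += flat * layer.units + layer.units
            flat = layer.units
    return total


# ---------------------------------------------------------------------------
# Convolution kernels (numpy, exact)
# ---------------------------------------------------------------------------


def _pad_spatial(x: np.ndarray, radii: tuple[int, int, int]) -> np.ndarray:
    r1, r2, r3 = radii
    return np.pad(x, ((0, 0), (r1, r1), (r2, r2), (r3, r3), (0, 0)))


def _conv3d_batch(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Same-padded 3D convolution of (N,W,L,D,Ci) with (k1,k2,k3,Ci,Co)."""
    k = kernels.shape[:3]
    radii = tuple(ki // 2 for ki in k)
    flipped = kernels[::-1, ::-1, ::-1]  # mathematical convolution
    xp = _pad_spatial(x, radii)
    windows = sliding_window_view(xp, k, axis=(1, 2, 3))
    return np.tensordot(windows, flipped, axes=([5, 6, 7, 4], [0, 1, 2, 3])) + biases


def _conv3d_backward(
    x: np.ndarray, kernels: np.ndarray, dout: np.ndarray, need_dx: bool = True
) -> tuple[Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Gradients (dx, dkernels, dbiases) of the same-padded convolution.

    Shift-and-accumulate over the kernel offsets: each offset contributes one
    channel-mixing matmul, which avoids materializing the full sliding-window
    expansion of the (wider) output gradient.
    """
    k = kernels.shape[:3]
    radii = tuple(ki // 2 for ki in k)
    flipped = kernels[::-1, ::-1, ::-1]
    xp = _pad_spatial(x, radii)
    n, w, l, d, _ = x.shape
    dflipped = np.empty_like(flipped)
    dxp = np.zeros_like(xp) if need_dx else None
    for a in range(k[0]):
        for b in range(k[1]):
            for c in range(k[2]):
                xs = xp[:, a : a + w, b : b + l, c : c + d, :]
                dflipped[a, b, c] = np.tensordot(
                    xs, dout, axes=([0, 1, 2, 3], [0, 1, 2, 3])
                )
                if need_dx:
                    dxp[:, a : a + w, b : b + l, c : c + d, :] += (
                        dout @ flipped[a, b, c].T
                    )
    dkernels = dflipped[::-1, ::-1, ::-1]
    dbiases = dout.sum(axis=(0, 1, 2, 3))
    dx = None
    if need_dx:
        dx = dxp[
            :, radii[0] : radii[0] + w, radii[1] : radii[1] + l, radii[2] : radii[2] + d, :
        ]
    return dx, dkernels, dbiases


def conv3d_forward(
    input: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """Single-volume 3D convolution layer: sliding triple sum, bias, activation.

    ``input`` is (W, L, D, C_in), ``kernels`` is (k1, k2, k3, C_in, C_out) with
    odd spatial dims (centered same zero padding), ``biases`` has one entry per
    output map. The inner product follows the convolution definition (kernel
    reflected); ``activation`` is ``"relu"`` or ``"none"``.
    """
    input = np.asarray(input, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)
    if input.ndim != 4:
        raise ValueError(f"input must be 4D (W,L,D,C), got shape {input.shape}")
    if kernels.ndim != 5:
        raise ValueError(f"kernels must be 5D (k,k,k,Cin,Cout), got {kernels.shape}")
    if any(k % 2 == 0 for k in kernels.shape[:3]):
        raise ValueError("kernel spatial dims must be odd for centered padding")
    if kernels.shape[3] != input.shape[3]:
        raise ValueError(
            f"kernel expects {kernels.shape[3]} input maps, input has {input.shape[3]}"
        )
    if biases.shape != (kernels.shape[4],):
        raise ValueError("biases must have one entry per output map")
    out = _conv3d_batch(input[None], kernels, biases)[0]
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation != "none":
        raise ValueError(f"unknown activation {activation!r}")
    return out


# ---------------------------------------------------------------------------
# Trainable network
# ---------------------------------------------------------------------------


def _init_std(std, fan_in: int) -> float:
    """Gaussian init scale: a number, or "he" for sqrt(2/fan_in)."""
    if std == "he":
        return float(np.sqrt(2.0 / fan_in))
    return float(std)


class _ConvLayer:
    def __init__(self, spec: Conv3D, in_channels: int, rng: np.random.Generator,
                 std, dtype=np.float32):
        k1, k2, k3 = spec.kernel
        self.spec = spec
        sd = _init_std(std, k1 * k2 * k3 * in_channels)
        self.params = {
            "kernels": rng.normal(
                0.0, sd, size=(k1, k2, k3, in_channels, spec.filters)
            ).astype(dtype),
            "biases": np.zeros(spec.filters, dtype=dtype),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._x: Optional[np.ndarray] = None
        self._mask: Optional[np.ndarray] = None
        self.needs_input_grad = True  # cleared for the first layer

    def forward(self, x, train, rng):
        self._x = x
        z = _conv3d_batch(x, self.params["kernels"], self.params["biases"])
        self._mask = z > 0
        return np.maximum(z, 0)

    def backward(self, dout):
        dout = dout * self._mask
        dx, dk, db = _conv3d_backward(
            self._x, self.params["kernels"], dout, need_dx=self.needs_input_grad
        )
        self.grads = {"kernels": dk, "biases": db}
        self._x = self._mask = None
        return dx


class _PoolLayer:
    def __init__(self, spec: MaxPool3D):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train, rng):
        s = self.spec.stride
        n, w, l, d, c = x.shape
        w2, l2, d2 = -(-w // s), -(-l // s), -(-d // s)
        pad = ((0, 0), (0, w2 * s - w), (0, l2 * s - l), (0, d2 * s - d), (0, 0))
        xp = np.pad(x, pad, constant_values=-np.inf)
        xr = xp.reshape(n, w2, s, l2, s, d2, s, c)
        windows = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, w2, l2, d2, c, s**3)
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.spec.stride
        n, w, l, d, c = self._in_shape
        w2, l2, d2 = -(-w // s), -(-l // s), -(-d // s)
        g = np.zeros((n, w2, l2, d2, c, s**3), dtype=dout.dtype)
        np.put_along_axis(g, self._argmax[..., None], dout[..., None], axis=-1)
        g = g.reshape(n, w2, l2, d2, c, s, s, s).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        g = g.reshape(n, w2 * s, l2 * s, d2 * s, c)
        return g[:, :w, :l, :d, :]


class _FlattenLayer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _DenseLayer:
    def __init__(self, spec: Dense, in_features: int, rng, std, relu: bool,
                 dtype=np.float32):
        self.spec = spec
        self.relu = relu
        sd = _init_std(std, in_features)
        self.params = {
            "weights": rng.normal(0.0, sd, size=(in_features, spec.units)).astype(dtype),
            "biases": np.zeros(spec.units, dtype=dtype),
        }
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.params["weights"] + self.params["biases"]
        if self.relu:
            self._mask = z > 0
            return np.maximum(z, 0)
        return z

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.grads = {
            "weights": self._x.T @ dout,
            "biases": dout.sum(axis=0),
        }
        dx = dout @ self.params["weights"].T
        self._x = None
        return dx


class _DropoutLayer:
    def __init__(self, spec: Dropout):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, train, rng):
        if not train or self.spec.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            rng = np.random.default_rng()
        keep = 1.0 - self.spec.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Network:
    """A trainable instance of an :class:`ArchitectureSpec`.

    Kernels are initialized from a zero-mean Gaussian; the default scale is
    fan-in adjusted (std = sqrt(2/fan_in) per layer) so activations keep a
    stable magnitude through the conv stack, and any fixed numeric std can be
    passed instead. Biases start at zero. Inputs to :meth:`forward` are ``(N, W, L, D)`` or
    ``(N, W, L, D, 1)`` float arrays; outputs are pre-softmax logits, one row
    per input. Softmax lives inside the loss for numerical stability.
    """

    def __init__(
        self,
        spec: ArchitectureSpec,
        input_shape: Sequence[int] = (50, 50, 28),
        seed: Optional[int] = None,
        init_std="he",
        dtype=np.float32,
    ):
        self.spec = spec
        self.input_shape = tuple(int(s) for s in input_shape)
        self.init_std = init_std if init_std == "he" else float(init_std)
        self.dtype = np.dtype(dtype)
        #: optional mean input volume (W, L, D, 1), subtracted before layer 0;
        #: set by the trainer from training data (mean-image centering)
        self.input_mean: Optional[np.ndarray] = None
        rng = np.random.default_rng(seed)
        self.layers = []
        channels = 1
        w, l, d = self.input_shape
        flat: Optional[int] = None
        for layer in spec.layers:
            if isinstance(layer, Conv3D):
                self.layers.append(_ConvLayer(layer, channels, rng, init_std, self.dtype))
                channels = layer.filters
            elif isinstance(layer, MaxPool3D):
                self.layers.append(_PoolLayer(layer))
                s = layer.stride
                w, l, d = (-(-w // s), -(-l // s), -(-d // s))
            elif isinstance(layer, Flatten):
                self.layers.append(_FlattenLayer())
                flat = w * l * d * channels
            elif isinstance(layer, Dense):
                assert flat is not None
                is_last = layer is [x for x in spec.layers if isinstance(x, Dense)][-1]
                self.layers.append(
                    _DenseLayer(layer, flat, rng, init_std, relu=not is_last, dtype=self.dtype)
                )
                flat = layer.units
            elif isinstance(layer, Dropout):
                self.layers.append(_DropoutLayer(layer))
        # the input needs no gradient; skip the first layer's dx
        if isinstance(self.layers[0], _ConvLayer):
            self.layers[0].needs_input_grad = False

    # -- inference ----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        if x.ndim != 5 or x.shape[1:4] != self.input_shape or x.shape[4] != 1:
            raise ValueError(
                f"expected input batch of shape (N, {self.input_shape[0]}, "
                f"{self.input_shape[1]}, {self.input_shape[2]}), got {x.shape}"
            )
        if self.input_mean is not None:
            x = x - self.input_mean
        return x

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Logits for a batch; dropout is active only when ``train`` is True."""
        h = self._check_input(x)
        for layer in self.layers:
            h = layer.forward(h, train, rng)
        return h

    def layer_activations(self, x: np.ndarray) -> list[tuple[LayerSpec, np.ndarray]]:
        """Post-activation output of every layer for one batch (eval mode)."""
        h = self._check_input(x)
        out = []
        for layer, spec_layer in zip(self.layers, self.spec.layers):
            h = layer.forward(h, False, None)
            out.append((spec_layer, h))
        return out

    # -- training -----------------------------------------------------------

    def loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        rng: Optional[np.random.Generator] = None,
    ) -> float:
        """Mean softmax cross-entropy on a batch; fills every layer's .grads."""
        logits = self.forward(x, train=True, rng=rng).astype(np.float64)
        y = np.asarray(y, dtype=np.intp)
        n = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=1))
        loss = float(np.mean(logsumexp - shifted[np.arange(n), y]))
        probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        g = dlogits.astype(self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
        return out

    @property
    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.grads.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(values[f"layer{i}.{name}"], dtype=self.dtype)

    def n_parameters(self) -> int:
        return sum(arr.size for arr in self.parameters.values())


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: Network, path) -> Path:
    """Portable checkpoint: weights plus the embedded architecture spec."""
    path = Path(path)
    meta = {
        "spec": net.spec.to_dict(),
        "input_shape": list(net.input_shape),
        "init_std": net.init_std,
        "dtype": net.dtype.name,
    }
    arrays = {k.replace(".", "__"): v for k, v in net.parameters.items()}
    if net.input_mean is not None:
        arrays["__input_mean__"] = net.input_mean
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path) -> Network:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {
            k.replace("__", "."): npz[k]
            for k in npz.files
            if k not in ("__meta__", "__input_mean__")
        }
        input_mean = npz["__input_mean__"] if "__input_mean__" in npz.files else None
    spec = ArchitectureSpec.from_dict(meta["spec"])
    net = Network(
        spec,
        input_shape=meta["input_shape"],
        seed=0,
        init_std=meta["init_std"],
        dtype=np.dtype(meta.get("dtype", "float32")),
    )
    net.set_parameters(arrays)
    net.input_mean = input_mean
    return net
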