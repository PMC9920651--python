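"""Temporal convolutional network architecture for heartbeat classification.

A TCN here is a stack of residual blocks.  Each block applies two identical
dilated causal convolutions (same filters and dilation), each followed by
channel-wise layer normalization and spatial dropout, with a ReLU after the
second normalization; a skip connection (a 1x1 convolution when the channel
counts differ, identity otherwise) adds the block input to its output.  The
dilation of block ``i`` (1-based) is ``2**(i-1)``, so the receptive field
grows exponentially with depth at constant parameter cost.  A dense head
reads the feature vector at the final time step and a softmax yields class
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import CausalConv1d, ChannelLayerNorm, Dense, ReLU, SpatialDropout, causal_pad, softmax

__all__ = [
    "ConvLayerSpec",
    "ResidualBlockSpec",
    "TCNSpec",
    "ResidualBlock",
    "TCNNetwork",
    "causal_pad",
    "dilated_causal_conv",
    "receptive_field_paper",
    "receptive_field_layer",
    "measure_receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """One dilated causal convolution: ``kernel_size`` taps per filter,
    ``in_channels`` -> ``out_channels``, tap spacing ``dilation``."""

    kernel_size: int
    in_channels: int
    out_channels: int
    dilation: int = 1

    def __post_init__(self):
        for name in ("kernel_size", "in_channels", "out_channels", "dilation"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Residual block: two identical convolutions, two norms, dropout,
    and a skip path (1x1 projection iff the channel count changes)."""

    kernel_size: int
    in_channels: int
    n_filters: int
    dilation: int
    dropout: float = 0.3

    @property
    def skip_projection(self) -> bool:
        return self.in_channels != self.n_filters

    @property
    def conv1(self) -> ConvLayerSpec:
        return ConvLayerSpec(self.kernel_size, self.in_channels, self.n_filters, self.dilation)

    @property
    def conv2(self) -> ConvLayerSpec:
        return ConvLayerSpec(self.kernel_size, self.n_filters, self.n_filters, self.dilation)


@dataclass(frozen=True)
class TCNSpec:
    """Full architecture description; the model, its parameter count and
    its receptive field all derive from this object."""

    blocks: tuple[ResidualBlockSpec, ...]
    num_classes: int = 5
    input_length: int = 140
    input_channels: int = 1
    head: str = "last"  # "last": final time step features; "avg": global average pool

    def __post_init__(self):
        if self.head not in ("last", "avg"):
            raise ValueError(f"head must be 'last' or 'avg', got {self.head!r}")

    @classmethod
    def build(cls, n_blocks: int, n_filters: int, kernel_sizes, *,
              dropout: float = 0.3, num_classes: int = 5, input_length: int = 140,
              input_channels: int = 1, head: str = "last") -> "TCNSpec":
        """Build a spec from counts: block ``i`` (1-based) gets dilation
        ``2**(i-1)`` and kernel size ``kernel_sizes[i-1]``."""
        kernel_sizes = tuple(int(k) for k in kernel_sizes)
        if len(kernel_sizes) != n_blocks:
            raise ValueError(
                f"need one kernel size per block: {n_blocks} blocks, "
                f"{len(kernel_sizes)} kernel sizes")
        blocks = []
        in_ch = input_channels
        for i, k in enumerate(kernel_sizes, start=1):
            blocks.append(ResidualBlockSpec(k, in_ch, n_filters, 2 ** (i - 1), dropout))
            in_ch = n_filters
        return cls(tuple(blocks), num_classes=num_classes, input_length=input_length,
                   input_channels=input_channels, head=head)

    @property
    def n_filters(self) -> int:
        return self.blocks[-1].n_filters if self.blocks else self.input_channels

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        return tuple(b.kernel_size for b in self.blocks)

    @property
    def dilations(self) -> tuple[int, ...]:
        return tuple(b.dilation for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "n_blocks": len(self.blocks),
            "n_filters": self.n_filters,
            "kernel_sizes": list(self.kernel_sizes),
            "dropout": self.blocks[0].dropout if self.blocks else 0.0,
            "num_classes": self.num_classes,
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "head": self.head,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TCNSpec":
        return cls.build(d["n_blocks"], d["n_filters"], d["kernel_sizes"],
                         dropout=d.get("dropout", 0.3),
                         num_classes=d.get("num_classes", 5),
                         input_length=d.get("input_length", 140),
                         input_channels=d.get("input_channels", 1),
                         head=d.get("head", "last"))


def dilated_causal_conv(x: np.ndarray, weights: np.ndarray,
                        bias: np.ndarray | float = 0.0, dilation: int = 1,
                        pad: bool = True) -> np.ndarray:
    """Dilated causal convolution as a pure function.

    ``x`` is ``(batch, in_channels, time)`` (a 1D array is promoted to a
    single-sample, single-channel batch); ``weights`` is
    ``(out_channels, in_channels, k)`` (a 1D tap vector ``f`` is promoted to
    ``(1, 1, k)``).  Output at time ``t`` is
    ``sum_j f(j) * x(t - d*j) + bias`` over taps ``j = 0..k-1`` and input
    channels.  With ``pad=True`` the input is left-padded with
    ``(k-1)*d`` zeros so the length is preserved; without padding the
    output has length ``n - (k-1)*d``.
    """
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, None, :]
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 1:
        w = w[None, None, :]
    k = w.shape[2]
    if w.shape[1] != x.shape[1]:
        raise ValueError(
            f"filter expects {w.shape[1]} input channels, got {x.shape[1]}")
    d = dilation
    span = (k - 1) * d
    if pad:
        x = causal_pad(x, k, d)
    n_out = x.shape[2] - span
    if n_out < 1:
        raise ValueError("input shorter than the dilated filter span")
    y = np.zeros((x.shape[0], w.shape[0], n_out))
    for j in range(k):
        lo = span - d * j
        y += np.einsum("oi,bit->bot", w[:, :, j], x[:, :, lo:lo + n_out], optimize=True)
    y += np.atleast_1d(np.asarray(bias, dtype=np.float64))[:, None]
    return y[0, 0] if squeeze and y.shape[:2] == (1, 1) else y


def receptive_field_paper(l: int, k: int) -> int:
    """Receptive field ``2**l * (k - 1)`` of an ``l``-layer stack of
    kernel-``k`` dilated convolutions with doubling dilations, as printed;
    see :func:`measure_receptive_field` for the empirical span of an
    actual model."""
    if l < 1 or k < 1:
        raise ValueError(f"l and k must be >= 1, got l={l}, k={k}")
    return 2 ** l * (k - 1)


def receptive_field_layer(d: int, k: int) -> int:
    """Single-layer receptive field ``d * (k - 1)``."""
    if d < 1 or k < 1:
        raise ValueError(f"d and k must be >= 1, got d={d}, k={k}")
    return d * (k - 1)


class ResidualBlock(nn.Layer):
    """[conv -> norm -> spatial dropout] -> [conv -> norm -> ReLU ->
    spatial dropout], plus the skip path added after the second dropout."""

    def __init__(self, spec: ResidualBlockSpec, rng: np.random.Generator,
                 name: str = "block"):
        self.spec = spec
        c = spec
        self.conv1 = CausalConv1d(c.in_channels, c.n_filters, c.kernel_size,
                                  c.dilation, rng=rng, name=f"{name}.conv1")
        self.norm1 = ChannelLayerNorm(c.n_filters, name=f"{name}.norm1")
        self.drop1 = SpatialDropout(c.dropout, rng)
        self.conv2 = CausalConv1d(c.n_filters, c.n_filters, c.kernel_size,
                                  c.dilation, rng=rng, name=f"{name}.conv2")
        self.norm2 = ChannelLayerNorm(c.n_filters, name=f"{name}.norm2")
        self.relu = ReLU()
        self.drop2 = SpatialDropout(c.dropout, rng)
        self.skip = (CausalConv1d(c.in_channels, c.n_filters, 1, 1, rng=rng,
                                  name=f"{name}.skip")
                     if c.skip_projection else None)

    def params(self) -> list[nn.Param]:
        ps = (self.conv1.params() + self.norm1.params()
              + self.conv2.params() + self.norm2.params())
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.norm1.forward(h, training)
        h = self.drop1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.norm2.forward(h, training)
        h = self.relu.forward(h, training)
        h = self.drop2.forward(h, training)
        s = x if self.skip is None else self.skip.forward(x, training)
        if s.shape != h.shape:
            raise AssertionError(
                f"skip/main shape mismatch: {s.shape} vs {h.shape}")
        return h + s

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.drop2.backward(gy)
        g = self.relu.backward(g)
        g = self.norm2.backward(g)
        g = self.conv2.backward(g)
        g = self.drop1.backward(g)
        g = self.norm1.backward(g)
        g = self.conv1.backward(g)
        gs = gy if self.skip is None else self.skip.backward(gy)
        return g + gs


class TCNNetwork(nn.Layer):
    """Instantiated network: residual blocks, dense head, softmax."""

    def __init__(self, spec: TCNSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.blocks = [ResidualBlock(b, rng, name=f"block{i + 1}")
                       for i, b in enumerate(spec.blocks)]
        self.head = Dense(spec.n_filters, spec.num_classes, rng=rng, name="fc")
        self._dropout_rng = rng

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def _validate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:  # (batch, time) -> single channel
            x = x[:, None, :]
        if x.ndim != 3 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected (batch, {self.spec.input_channels}, time) input, "
                f"got shape {x.shape}")
        if x.shape[2] != self.spec.input_length:
            raise ValueError(
                f"expected sequences of length {self.spec.input_length}, "
                f"got {x.shape[2]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        return x

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-time-step features ``(batch, n_filters, time)`` before the head."""
        h = self._validate(x)
        for b in self.blocks:
            h = b.forward(h, training)
        return h

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.features(x, training)
        self._feat_shape = h.shape
        z = h[:, :, -1] if self.spec.head == "last" else h.mean(axis=2)
        return self.head.forward(z, training)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        gz = self.head.backward(glogits)
        gh = np.zeros(self._feat_shape)
        if self.spec.head == "last":
            gh[:, :, -1] = gz
        else:
            gh += gz[:, :, None] / self._feat_shape[2]
        for b in reversed(self.blocks):
            gh = b.backward(gh)
        return gh

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities per sample (rows sum to 1)."""
        return softmax(self.forward(x, training=False), axis=1)

    # -- weight (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing weight {p.name!r} in state dict")
            v = np.asarray(state[p.name], dtype=np.float64)
            if v.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: {v.shape} vs {p.value.shape}")
            p.value[...] = v


def tcn_forward(x: np.ndarray, spec: TCNSpec, training: bool = False,
                seed: int | None = None) -> np.ndarray:
    """Convenience wrapper: build a fresh network from ``spec`` and return
    class probabilities for ``x``."""
    return nn.softmax(TCNNetwork(spec, seed=seed).forward(x, training), axis=1)


def measure_receptive_field(model, position: int, *, x: np.ndarray | None = None,
                            delta: float = 1.0, atol: float = 0.0) -> int:
    """Empirically measure the receptive field at an output time step.

    Perturbs each input position in turn (inference mode) and counts how
    many positions at or before ``position`` change the channel-summed
    feature output there.  Raises if any position strictly after
    ``position`` has an effect, since that would break causality.

    ``model`` is a :class:`TCNNetwork` (its pre-head features are probed)
    or any layer with a ``forward(x, training=False)`` returning
    ``(batch, channels, time)``.
    """
    if isinstance(model, TCNNetwork):
        n = model.spec.input_length
        c = model.spec.input_channels
        fn = lambda a: model.features(a, training=False)
    else:
        if x is None:
            raise ValueError("a probe input `x` is required for bare layers")
        n = x.shape[-1]
        c = getattr(model, "in_channels", 1)
        fn = lambda a: model.forward(a, training=False)
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside [0, {n})")
    if x is None:
        x = np.zeros((1, c, n))
    else:
        x = np.asarray(x, dtype=np.float64).reshape(1, c, n)
    base = fn(x)[0].sum(axis=0)
    count = 0
    for i in range(n):
        xp = x.copy()
        xp[0, :, i] += delta
        out = fn(xp)[0].sum(axis=0)
        changed = abs(out[position] - base[position]) > atol
        if changed and i > position:
            raise AssertionError(
                f"causality violated: input {i} affects output {position}")
        count += changed
    return count


# -- checkpoints ------------------------------------------------------------------


def save_checkpoint(path, network: TCNNetwork, extra: dict | None = None) -> None:
    """Write weights plus the embedded architecture spec to an ``.npz``."""
    meta = {"spec": network.spec.to_dict(), "extra": extra or {}}
    arrays = {k.replace(".", "__"): v for k, v in network.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[TCNNetwork, dict]:
    """Rebuild a network (and its metadata) from :func:`save_checkpoint` output."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k.replace("__", "."): z[k] for k in z.files if k != "__meta__"}
    net = TCNNetwork(TCNSpec.from_dict(meta["spec"]))
    net.load_state_dict(state)
    return net, meta.get("extra", {})
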