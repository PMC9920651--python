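"""Learnable-parameter accounting for TCN architectures.

A convolution layer with kernel size ``KT``, ``FTp`` input channels and
``FT`` filters holds ``KT * FTp * FT`` weights plus ``FT`` biases; a
normalization layer holds one scale and one offset per channel
(``2 * FT``); a dense head mapping ``FT`` features to ``C`` classes holds
``FT * C + C``.  ``total_param_count`` rolls these up per block.

Two counting conventions are exposed.  The default
(``include_skip=False, include_head=True``) counts the two convolutions
and two normalizations per block plus the head — the convention under
which the published per-architecture totals are exactly reproduced.  The
deployed network additionally carries the first block's 1x1 skip
projection; count it with ``include_skip=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .tcn import TCNSpec

__all__ = [
    "conv_param_count",
    "norm_param_count",
    "fc_param_count",
    "LayerParams",
    "ParamBreakdown",
    "total_param_count",
    "format_kilo",
]


def conv_param_count(KT: int, FTp: int, FT: int) -> int:
    """Parameters of a convolution layer: ``KT * FTp * FT`` weights + ``FT`` biases."""
    if min(KT, FTp, FT) < 1:
        raise ValueError(f"all arguments must be >= 1, got ({KT}, {FTp}, {FT})")
    return KT * FTp * FT + FT


def norm_param_count(FT: int) -> int:
    """Parameters of a normalization layer: one beta and one gamma per channel."""
    if FT < 1:
        raise ValueError(f"FT must be >= 1, got {FT}")
    return 2 * FT


def fc_param_count(FT: int, num_classes: int) -> int:
    """Parameters of the dense head: ``FT * C`` weights + ``C`` biases."""
    if min(FT, num_classes) < 1:
        raise ValueError("FT and num_classes must be >= 1")
    return FT * num_classes + num_classes


def format_kilo(total: int) -> str:
    """Display a count in thousands: round half up to one decimal, strip '.0'."""
    k = Decimal(total) / Decimal(1000)
    k = k.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    s = str(k)
    return s[:-2] if s.endswith(".0") else s


@dataclass(frozen=True)
class LayerParams:
    """One row of the breakdown: a layer and its weight/bias split."""

    name: str
    kind: str  # "conv" | "norm" | "fc"
    weights: int
    biases: int

    @property
    def total(self) -> int:
        return self.weights + self.biases


@dataclass(frozen=True)
class ParamBreakdown:
    layers: tuple[LayerParams, ...]

    @property
    def total(self) -> int:
        return sum(l.total for l in self.layers)

    @property
    def total_kilo(self) -> float:
        return float(Decimal(self.total) / Decimal(1000))

    @property
    def kilo_label(self) -> str:
        return format_kilo(self.total) + " K"

    def as_rows(self) -> list[dict]:
        return [{"layer": l.name, "kind": l.kind, "W": l.weights, "B": l.biases,
                 "total": l.total} for l in self.layers]

    def table(self) -> str:
        w = max([len(l.name) for l in self.layers] + [len("layer")])
        lines = [f"{'layer':<{w}}  {'kind':<5} {'W':>8} {'B':>6} {'total':>8}"]
        for l in self.layers:
            lines.append(f"{l.name:<{w}}  {l.kind:<5} {l.weights:>8} {l.biases:>6} "
                         f"{l.total:>8}")
        lines.append(f"{'TOTAL':<{w}}  {'':<5} {'':>8} {'':>6} {self.total:>8}"
                     f"  ({self.kilo_label})")
        return "\n".join(lines)


def total_param_count(spec: TCNSpec, include_skip: bool = False,
                      include_head: bool = True) -> ParamBreakdown:
    """Per-layer parameter breakdown of an architecture.

    Per block: two convolutions (the first convolution of the first block
    sees the raw input channels, all others see ``FT``) and two
    normalizations.  ``include_skip`` adds each block's 1x1 projection
    where the channel count changes; ``include_head`` adds the dense head.
    """
    rows: list[LayerParams] = []
    for i, b in enumerate(spec.blocks, start=1):
        for j, conv in enumerate((b.conv1, b.conv2), start=1):
            w = conv.kernel_size * conv.in_channels * conv.out_channels
            rows.append(LayerParams(f"block{i}.conv{j}", "conv", w, conv.out_channels))
            rows.append(LayerParams(f"block{i}.norm{j}", "norm", b.n_filters,
                                    b.n_filters))
        if include_skip and b.skip_projection:
            rows.append(LayerParams(f"block{i}.skip", "conv",
                                    b.in_channels * b.n_filters, b.n_filters))
    if include_head and spec.blocks:
        rows.append(LayerParams("fc", "fc", spec.n_filters * spec.num_classes,
                                spec.num_classes))
    return ParamBreakdown(tuple(rows))
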