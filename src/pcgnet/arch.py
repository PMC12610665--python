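"""Analytic architecture accounting: shapes, parameters, FLOPs.

The weighted CNN (WCNN) is three unpadded 2x2 convolutions (32, 64 and 64
filters; strides 1, 1 and 2) each followed by batch normalization, the
parameter-free key-weighting-calculation (KWC) channel-rescaling layer, a
flatten, a 128-unit hidden dense layer and a softmax output.  Everything in
this module is derived analytically from the layer list:

* shapes:   Hout = floor((Hin - Kh) / stride) + 1 (valid convolution)
* params:   conv  (Kh*Kw*Cin + 1) * Cout,   dense  (in + 1) * out
* FLOPs:    conv  2*Kh*Kw*Cin*Hout*Wout*Cout,   dense  2*in*out

KWC, flatten, dropout and batch-norm layers contribute zero to both counts
(normalization parameters are negligible and conventionally excluded).  For
the default 17x13x1 input this yields per-layer parameter counts
160 / 8256 / 16448 / 286848 / 645 (total 312,357), a flatten size of 2240 and
4,474,112 forward FLOPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "default_architecture",
    "forward_shapes",
    "count_parameters",
    "count_flops",
]


@dataclass
class LayerSpec:
    """One layer of the architecture.

    ``kind`` is one of ``conv``, ``kwc``, ``flatten``, ``dense``, ``dropout``.
    Conv layers use ``kernel`` (Kh, Kw), ``stride`` and ``out_channels``;
    dense layers use ``out_units``.
    """

    kind: str
    out_channels: int = 0
    kernel: tuple[int, int] = (2, 2)
    stride: int = 1
    activation: str = "relu"
    batch_norm: bool = False
    out_units: int = 0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "kwc", "flatten", "dense", "dropout"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv":
            if min(self.kernel) < 1 or self.stride < 1 or self.out_channels < 1:
                raise ValueError("conv kernel, stride and out_channels must be positive")
        if self.kind == "dense" and self.out_units < 1:
            raise ValueError("dense out_units must be positive")


@dataclass
class ArchitectureSpec:
    """Ordered layer list plus the input feature-map geometry.

    ``input_shape`` is (dims, frames, channels) of the MFCC map.
    """

    input_shape: tuple[int, int, int]
    layers: list[LayerSpec] = field(default_factory=list)
    n_classes: int = 5

    def __post_init__(self) -> None:
        if min(self.input_shape) < 1:
            raise ValueError("input_shape entries must be positive")


def default_architecture(
    dims: int = 17,
    frames: int = 13,
    n_classes: int = 5,
    use_kwc: bool = True,
    dropout: float = 0.3,
) -> ArchitectureSpec:
    """The WCNN layer list for a ``dims`` x ``frames`` x 1 input."""
    layers = [
        LayerSpec("conv", out_channels=32, kernel=(2, 2), stride=1, batch_norm=True),
        LayerSpec("conv", out_channels=64, kernel=(2, 2), stride=1, batch_norm=True),
        LayerSpec("conv", out_channels=64, kernel=(2, 2), stride=2, batch_norm=True),
        LayerSpec("dropout", rate=dropout),
    ]
    if use_kwc:
        layers.append(LayerSpec("kwc"))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", out_units=128),
        LayerSpec("dropout", rate=dropout),
        LayerSpec("dense", out_units=n_classes, activation="softmax"),
    ]
    return ArchitectureSpec(input_shape=(dims, frames, 1), layers=layers, n_classes=n_classes)


def _conv_out(size: int, kernel: int, stride: int) -> int:
    out = (size - kernel) // stride + 1
    if size < kernel or out < 1:
        raise ValueError(f"kernel {kernel} does not fit input extent {size}")
    return out


def forward_shapes(arch: ArchitectureSpec) -> list:
    """Shape after each layer: (H, W, C) tuples, or an int after flatten/dense.

    Raises on dimension underflow (kernel larger than its input).
    """
    h, w, c = arch.input_shape
    flat: int | None = None
    shapes: list = []
    for layer in arch.layers:
        if layer.kind == "conv":
            if flat is not None:
                raise ValueError("conv layer after flatten")
            h = _conv_out(h, layer.kernel[0], layer.stride)
            w = _conv_out(w, layer.kernel[1], layer.stride)
            c = layer.out_channels
            shapes.append((h, w, c))
        elif layer.kind in ("kwc", "dropout"):
            shapes.append((h, w, c) if flat is None else flat)
        elif layer.kind == "flatten":
            flat = h * w * c
            shapes.append(flat)
        elif layer.kind == "dense":
            if flat is None:
                raise ValueError("dense layer requires a flatten first")
            flat = layer.out_units
            shapes.append(flat)
    return shapes


def count_parameters(arch: ArchitectureSpec, per_layer: bool = False):
    """Trainable parameter total: conv (Kh*Kw*Cin+1)*Cout + dense (in+1)*out.

    KWC, flatten, dropout and batch normalization contribute zero.
    """
    h, w, c = arch.input_shape
    flat: int | None = None
    counts: list[int] = []
    for layer in arch.layers:
        if layer.kind == "conv":
            kh, kw = layer.kernel
            counts.append((kh * kw * c + 1) * layer.out_channels)
            h = _conv_out(h, kh, layer.stride)
            w = _conv_out(w, kw, layer.stride)
            c = layer.out_channels
        elif layer.kind == "flatten":
            flat = h * w * c
            counts.append(0)
        elif layer.kind == "dense":
            counts.append((flat + 1) * layer.out_units)
            flat = layer.out_units
        else:
            counts.append(0)
    if per_layer:
        return counts
    return sum(counts)


def count_flops(arch: ArchitectureSpec) -> int:
    """Forward-pass FLOPs: conv 2*Kh*Kw*Cin*Hout*Wout*Cout + dense 2*in*out."""
    h, w, c = arch.input_shape
    flat: int | None = None
    total = 0
    for layer in arch.layers:
        if layer.kind == "conv":
            kh, kw = layer.kernel
            h = _conv_out(h, kh, layer.stride)
            w = _conv_out(w, kw, layer.stride)
            total += 2 * kh * kw * c * h * w * layer.out_channels
            c = layer.out_channels
        elif layer.kind == "flatten":
            flat = h * w * c
        elif layer.kind == "dense":
            total += 2 * flat * layer.out_units
            flat = layer.out_units
    return total
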