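"""Executable residual encoder-decoder segmentation network.

The encoder alternates transition blocks (3x3 conv -> BN -> ReLU -> 2x2
max-pool, halving the spatial dims) with pre-activation residual blocks
(BN -> ReLU -> 1x1 conv -> BN -> ReLU -> 3x3 conv, merged with the block
input so the channel count doubles). A bottleneck bridge repeats the pair
once more and then compresses the 1024 feature maps to 64 with a 1x1
convolution before the decoder, which upsamples, concatenates the matching
transition-block output and convolves back up to full resolution, ending in
a 1x1 convolution with a sigmoid that emits a per-pixel lesion probability
map the same size as the input slice.
"""

from __future__ import annotations

import numpy as np

from ..errors import ArchitectureError, ShapeError
from ..nn import BatchNorm, Conv2D, Dropout, MaxPool2x2, ReLU, Sigmoid, Upsample2x
from .base import Network
from .convention import BlockConvention, DEFAULT_CONVENTION
from .spec import ModelSpec, cnnres_spec

# Published row-by-row output schedule for the default geometry
# (160x160x1 input, 4 encoder levels, 32 base filters).
PUBLISHED_SCHEDULE: list[tuple[str, tuple[int, int, int]]] = [
    ("Input", (160, 160, 1)),
    ("Transition Block 1", (80, 80, 32)),
    ("Residual Block 1", (80, 80, 64)),
    ("Transition Block 2", (40, 40, 64)),
    ("Residual Block 2", (40, 40, 128)),
    ("Transition Block 3", (20, 20, 128)),
    ("Residual Block 3", (20, 20, 256)),
    ("Transition Block 4", (10, 10, 256)),
    ("Residual Block 4", (10, 10, 512)),
    ("Bottleneck (transition)", (5, 5, 512)),
    ("Bottleneck (residual)", (5, 5, 1024)),
    ("Bottleneck (compress)", (5, 5, 64)),
    ("Upsampling 1", (10, 10, 64)),
    ("Concatenate 1", (10, 10, 320)),
    ("Conv 1", (10, 10, 256)),
    ("Upsampling 2", (20, 20, 256)),
    ("Concatenate 2", (20, 20, 384)),
    ("Conv 2", (20, 20, 128)),
    ("Upsampling 3", (40, 40, 128)),
    ("Concatenate 3", (40, 40, 192)),
    ("Conv 3", (40, 40, 64)),
    ("Upsampling 4", (80, 80, 64)),
    ("Concatenate 4", (80, 80, 96)),
    ("Conv 4", (80, 80, 64)),
    ("Conv 5", (80, 80, 32)),
    ("Upsampling 5", (160, 160, 32)),
    ("Conv5", (160, 160, 1)),
    ("Output", (160, 160, 1)),
]


class _ResidualBlock:
    """Pre-activation residual unit; owns its layers, wired by the network."""

    def __init__(self, net: Network, idx: str, channels: int, cv: BlockConvention):
        inner = cv.inner_width(channels)
        self.combine = cv.combine
        reg = net._register
        bn_kw = dict(eps=cv.bn_epsilon, momentum=cv.bn_momentum)
        self.bn1 = reg(f"{idx}/bn1", BatchNorm(channels, **bn_kw))
        self.relu1 = reg(f"{idx}/relu1", ReLU())
        self.conv1 = reg(f"{idx}/conv1", Conv2D(channels, inner, 1, bias=cv.conv_bias, rng=net.rng))
        self.bn2 = reg(f"{idx}/bn2", BatchNorm(inner, **bn_kw))
        self.relu2 = reg(f"{idx}/relu2", ReLU())
        out = channels if cv.combine == "concatenate" else 2 * channels
        self.conv2 = reg(f"{idx}/conv2", Conv2D(inner, out, 3, bias=cv.conv_bias, rng=net.rng))
        self.proj = None
        if cv.combine == "projected_add":
            self.proj = reg(f"{idx}/proj",
                            Conv2D(channels, 2 * channels, 1, bias=cv.conv_bias, rng=net.rng))
        self.channels = channels

    def forward(self, x, training):
        f = self.bn1.forward(x, training)
        f = self.relu1.forward(f, training)
        f = self.conv1.forward(f, training)
        f = self.bn2.forward(f, training)
        f = self.relu2.forward(f, training)
        f = self.conv2.forward(f, training)
        if self.combine == "concatenate":
            return np.concatenate([x, f], axis=-1)
        return self.proj.forward(x, training) + f

    def backward(self, dout):
        if self.combine == "concatenate":
            dx_direct = dout[..., :self.channels]
            df = dout[..., self.channels:]
        else:
            dx_direct = self.proj.backward(dout)
            df = dout
        df = self.conv2.backward(df)
        df = self.relu2.backward(df)
        df = self.bn2.backward(df)
        df = self.conv1.backward(df)
        df = self.relu1.backward(df)
        df = self.bn1.backward(df)
        return dx_direct + df


class CNNRes(Network):
    """Residual encoder-decoder network with a compressing bottleneck.

    ``levels``, ``base_filters`` and ``input_size`` default to the published
    geometry; smaller values build reduced variants with the same block
    grammar (used for cheap tests). Construction validates the resulting
    per-block output schedule against the published table whenever the
    default geometry is requested and raises :class:`ArchitectureError`
    naming the first deviating row.
    """

    def __init__(self, convention: BlockConvention = DEFAULT_CONVENTION, *,
                 input_size: int = 160, in_channels: int = 1,
                 levels: int = 4, base_filters: int = 32,
                 dropout_rate: float = 0.5, output_bias_init: float = -2.0,
                 seed: int | None = 0):
        super().__init__(seed)
        self.convention = convention
        self.input_size = input_size
        self.in_channels = in_channels
        self.levels = levels
        self.base_filters = base_filters
        self.spec: ModelSpec = cnnres_spec(convention, input_size=input_size,
                                           in_channels=in_channels, levels=levels,
                                           base_filters=base_filters)
        cv = convention
        bn_kw = dict(eps=cv.bn_epsilon, momentum=cv.bn_momentum)
        reg = self._register

        self.enc = []
        cin = in_channels
        for lv in range(1, levels + 1):
            cout = base_filters if lv == 1 else cin
            idx = f"transition{lv}"
            block = {
                "conv": reg(f"{idx}/conv", Conv2D(cin, cout, 3, bias=cv.conv_bias, rng=self.rng)),
                "bn": reg(f"{idx}/bn", BatchNorm(cout, **bn_kw)),
                "relu": reg(f"{idx}/relu", ReLU()),
                "pool": reg(f"{idx}/pool", MaxPool2x2()),
                "res": _ResidualBlock(self, f"residual{lv}", cout, cv),
            }
            self.enc.append(block)
            cin = 2 * cout

        idx = "bottleneck/transition"
        self.bott_conv = reg(f"{idx}/conv", Conv2D(cin, cin, 3, bias=cv.conv_bias, rng=self.rng))
        self.bott_bn = reg(f"{idx}/bn", BatchNorm(cin, **bn_kw))
        self.bott_relu = reg(f"{idx}/relu", ReLU())
        self.bott_pool = reg(f"{idx}/pool", MaxPool2x2())
        self.bott_res = _ResidualBlock(self, "bottleneck/residual", cin, cv)
        cin = 2 * cin

        self.compress_bn = reg("compress/bn", BatchNorm(cin, **bn_kw)) if cv.compress_bn else None
        self.compress_relu = reg("compress/relu", ReLU())
        compress_out = 2 * base_filters
        self.compress_conv = reg("compress/conv",
                                 Conv2D(cin, compress_out, 1, bias=cv.conv_bias, rng=self.rng))
        self.compress_drop = reg("compress/dropout", Dropout(dropout_rate, rng=self.rng))

        self.dec = []
        cin = compress_out
        # skip j feeds decoder stage j counted from the bottleneck outwards
        skip_channels = [blk["res"].channels for blk in self.enc]
        for j, lv in enumerate(range(levels, 0, -1), start=1):
            skip = skip_channels[lv - 1]
            cout = skip if lv > 1 else 2 * base_filters
            idx = f"decoder{j}"
            self.dec.append({
                "up": reg(f"{idx}/up", Upsample2x()),
                "conv": reg(f"{idx}/conv",
                            Conv2D(cin + skip, cout, 3, bias=cv.conv_bias, rng=self.rng)),
                "relu": reg(f"{idx}/relu", ReLU()),
                "skip_ch": skip,
            })
            cin = cout

        self.head_conv = reg("head/conv", Conv2D(cin, base_filters, 3,
                                                 bias=cv.conv_bias, rng=self.rng))
        self.head_relu = reg("head/relu", ReLU())
        self.head_up = reg(f"decoder{levels + 1}/up", Upsample2x())
        self.head_out = reg("head/conv_out", Conv2D(base_filters, 1, 1,
                                                    bias=cv.conv_bias, rng=self.rng))
        if self.head_out.b is not None:
            # start the sigmoid head at the (low) foreground prior so early
            # optimisation is not dominated by pushing background logits down
            self.head_out.b.value[:] = output_bias_init
        self.head_sigmoid = reg("head/sigmoid", Sigmoid())

        self._validate_schedule()

    def _validate_schedule(self) -> None:
        if (self.input_size, self.in_channels, self.levels, self.base_filters) != (160, 1, 4, 32):
            return
        built = self.spec.block_output_shapes()
        for (row, expected), (brow, bshape) in zip(PUBLISHED_SCHEDULE, built):
            if bshape != expected:
                raise ArchitectureError(
                    f"row {row!r}: constructed output {bshape} deviates from "
                    f"the published {expected}")
        if len(built) != len(PUBLISHED_SCHEDULE):
            raise ArchitectureError("constructed schedule length deviates from the published table")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.input_size or x.shape[2] != self.input_size \
                or x.shape[3] != self.in_channels:
            raise ShapeError(
                f"expected input (B, {self.input_size}, {self.input_size}, "
                f"{self.in_channels}), got {x.shape}")
        h = np.asarray(x, dtype=np.float32)
        self._skips = []
        for blk in self.enc:
            h = blk["conv"].forward(h, training)
            h = blk["bn"].forward(h, training)
            h = blk["relu"].forward(h, training)
            h = blk["pool"].forward(h, training)
            self._skips.append(h)
            h = blk["res"].forward(h, training)
        h = self.bott_conv.forward(h, training)
        h = self.bott_bn.forward(h, training)
        h = self.bott_relu.forward(h, training)
        h = self.bott_pool.forward(h, training)
        h = self.bott_res.forward(h, training)
        if self.compress_bn is not None:
            h = self.compress_bn.forward(h, training)
        h = self.compress_relu.forward(h, training)
        h = self.compress_conv.forward(h, training)
        h = self.compress_drop.forward(h, training)
        for j, blk in enumerate(self.dec):
            h = blk["up"].forward(h, training)
            skip = self._skips[self.levels - 1 - j]
            h = np.concatenate([skip, h], axis=-1)
            h = blk["conv"].forward(h, training)
            h = blk["relu"].forward(h, training)
        h = self.head_conv.forward(h, training)
        h = self.head_relu.forward(h, training)
        h = self.head_up.forward(h, training)
        h = self.head_out.forward(h, training)
        return self.head_sigmoid.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head_sigmoid.backward(dout)
        d = self.head_out.backward(d)
        d = self.head_up.backward(d)
        d = self.head_relu.backward(d)
        d = self.head_conv.backward(d)
        dskips = [None] * self.levels
        for j in range(len(self.dec) - 1, -1, -1):
            blk = self.dec[j]
            d = blk["relu"].backward(d)
            d = blk["conv"].backward(d)
            skip_ch = blk["skip_ch"]
            dskips[self.levels - 1 - j] = d[..., :skip_ch]
            d = blk["up"].backward(d[..., skip_ch:])
        d = self.compress_drop.backward(d)
        d = self.compress_conv.backward(d)
        d = self.compress_relu.backward(d)
        if self.compress_bn is not None:
            d = self.compress_bn.backward(d)
        d = self.bott_res.backward(d)
        d = self.bott_pool.backward(d)
        d = self.bott_relu.backward(d)
        d = self.bott_bn.backward(d)
        d = self.bott_conv.backward(d)
        for lv in range(self.levels - 1, -1, -1):
            blk = self.enc[lv]
            d = blk["res"].backward(d)
            d = d + dskips[lv]
            d = blk["pool"].backward(d)
            d = blk["relu"].backward(d)
            d = blk["bn"].backward(d)
            d = blk["conv"].backward(d)
        return d

    def trace_block_shapes(self, batch: int = 1) -> list[tuple[str, tuple[int, int, int]]]:
        """Per-block output shapes observed on a real forward pass, in the
        row order of the published table (independent of the arithmetic spec)."""
        x = np.zeros((batch, self.input_size, self.input_size, self.in_channels),
                     dtype=np.float32)
        rows: list[tuple[str, tuple]] = [("Input", tuple(x.shape[1:]))]
        h = x
        for lv, blk in enumerate(self.enc, start=1):
            h = blk["pool"].forward(blk["relu"].forward(
                blk["bn"].forward(blk["conv"].forward(h))))
            rows.append((f"Transition Block {lv}", tuple(h.shape[1:])))
            skip = h
            h = blk["res"].forward(h, False)
            rows.append((f"Residual Block {lv}", tuple(h.shape[1:])))
            blk["_skip"] = skip
        h = self.bott_pool.forward(self.bott_relu.forward(
            self.bott_bn.forward(self.bott_conv.forward(h))))
        rows.append(("Bottleneck (transition)", tuple(h.shape[1:])))
        h = self.bott_res.forward(h, False)
        rows.append(("Bottleneck (residual)", tuple(h.shape[1:])))
        if self.compress_bn is not None:
            h = self.compress_bn.forward(h)
        h = self.compress_conv.forward(self.compress_relu.forward(h))
        rows.append(("Bottleneck (compress)", tuple(h.shape[1:])))
        for j, blk in enumerate(self.dec, start=1):
            h = blk["up"].forward(h)
            rows.append((f"Upsampling {j}", tuple(h.shape[1:])))
            h = np.concatenate([self.enc[self.levels - j]["_skip"], h], axis=-1)
            rows.append((f"Concatenate {j}", tuple(h.shape[1:])))
            h = blk["relu"].forward(blk["conv"].forward(h))
            rows.append((f"Conv {j}", tuple(h.shape[1:])))
        h = self.head_relu.forward(self.head_conv.forward(h))
        rows.append(("Conv 5", tuple(h.shape[1:])))
        h = self.head_up.forward(h)
        rows.append((f"Upsampling {self.levels + 1}", tuple(h.shape[1:])))
        h = self.head_sigmoid.forward(self.head_out.forward(h))
        rows.append(("Conv5", tuple(h.shape[1:])))
        rows.append(("Output", tuple(h.shape[1:])))
        return rows


def build_cnnres(convention: BlockConvention = DEFAULT_CONVENTION,
                 **kwargs) -> tuple[CNNRes, ModelSpec]:
    """Construct the network and return it with its arithmetic layer table."""
    model = CNNRes(convention, **kwargs)
    return model, model.spec
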