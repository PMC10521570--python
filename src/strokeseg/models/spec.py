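"""Closed-form layer tables and parameter accounting for both architectures.

These tables are computed purely arithmetically — kernel x kernel x C_in x
C_out (+ C_out for a bias) per convolution, 2C trainable + 2C running-stat
parameters per batch-normalisation layer — and never touch the executable
models, so they serve as an independent audit of the parameter arrays the
layer engine actually allocates.

``PUBLISHED_*`` constants are the parameter totals printed in the source
publication; :func:`reconcile_conventions` sweeps the enumerated convention
space and reports each convention's distance to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..errors import ArchitectureError
from .convention import BlockConvention, COMBINE_MODES, DEFAULT_CONVENTION

# Parameter totals printed for the residual encoder-decoder model and the
# reference U-Net in the source publication.
PUBLISHED_TRAINABLE = 6_465_153
PUBLISHED_NON_TRAINABLE = 5_952
PUBLISHED_TOTAL = 6_471_105
PUBLISHED_UNET_TOTAL = 31_031_685


@dataclass(frozen=True)
class LayerRecord:
    name: str          # unique layer path, e.g. "transition1/conv"
    block: str         # row name in the published table, e.g. "Transition Block 1"
    kind: str          # conv / bn / relu / maxpool / upsample / concat / add / dropout / sigmoid / input
    kernel: tuple | None
    stride: int
    in_shape: tuple    # (H, W, C); concat layers carry the primary input
    out_shape: tuple
    trainable: int
    non_trainable: int


@dataclass
class ModelSpec:
    """Ordered layer records plus aggregate parameter totals."""

    name: str
    records: list[LayerRecord] = field(default_factory=list)

    @property
    def trainable(self) -> int:
        return sum(r.trainable for r in self.records)

    @property
    def non_trainable(self) -> int:
        return sum(r.non_trainable for r in self.records)

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    def block_output_shapes(self) -> list[tuple[str, tuple]]:
        """(block name, output shape) for the last layer of each block —
        the per-row schedule of the published architecture table."""
        out: list[tuple[str, tuple]] = []
        for r in self.records:
            if out and out[-1][0] == r.block:
                out[-1] = (r.block, r.out_shape)
            else:
                out.append((r.block, r.out_shape))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


@dataclass
class ParamCountReport:
    trainable: int
    non_trainable: int
    per_layer: pd.DataFrame

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


def conv_params(kernel: int, cin: int, cout: int, bias: bool) -> int:
    return kernel * kernel * cin * cout + (cout if bias else 0)


def bn_params(channels: int) -> tuple[int, int]:
    """(trainable, non_trainable): scale+shift vs running mean+variance."""
    return 2 * channels, 2 * channels


class _Table:
    """Accumulates layer records while tracking the current tensor shape."""

    def __init__(self, h: int, w: int, c: int):
        self.records: list[LayerRecord] = []
        self.shape = (h, w, c)

    def add(self, name, block, kind, kernel, stride, out_shape, trainable=0, non_trainable=0,
            in_shape=None):
        rec = LayerRecord(name, block, kind, kernel, stride,
                          in_shape if in_shape is not None else self.shape,
                          tuple(out_shape), trainable, non_trainable)
        self.records.append(rec)
        self.shape = tuple(out_shape)


def cnnres_spec(convention: BlockConvention = DEFAULT_CONVENTION, *,
                input_size: int = 160, in_channels: int = 1,
                levels: int = 4, base_filters: int = 32) -> ModelSpec:
    """Layer table for the residual encoder-decoder segmentation network.

    ``levels``/``base_filters``/``input_size`` default to the published
    architecture (4 encoder levels, 32 base filters, 160x160 input); smaller
    values build reduced variants with the same block grammar. Spatial dims
    must survive ``levels + 1`` halvings (the extra one is the bottleneck).
    """
    if input_size % (2 ** (levels + 1)) != 0:
        raise ArchitectureError(
            f"input size {input_size} is not divisible by 2^{levels + 1}; "
            "every transition block and the bottleneck halve the spatial dims")
    t = _Table(input_size, input_size, in_channels)
    t.add("input", "Input", "input", None, 1, t.shape)
    cv = convention

    def transition(idx: int, block: str, cout: int):
        h, w, c = t.shape
        t.add(f"{idx}/conv", block, "conv", (3, 3), 1, (h, w, cout),
              conv_params(3, c, cout, cv.conv_bias))
        tr, nt = bn_params(cout)
        t.add(f"{idx}/bn", block, "bn", None, 1, (h, w, cout), tr, nt)
        t.add(f"{idx}/relu", block, "relu", None, 1, (h, w, cout))
        t.add(f"{idx}/pool", block, "maxpool", (2, 2), 2, (h // 2, w // 2, cout))

    def residual(idx: int, block: str):
        h, w, c = t.shape
        inner = cv.inner_width(c)
        tr, nt = bn_params(c)
        t.add(f"{idx}/bn1", block, "bn", None, 1, (h, w, c), tr, nt)
        t.add(f"{idx}/relu1", block, "relu", None, 1, (h, w, c))
        t.add(f"{idx}/conv1", block, "conv", (1, 1), 1, (h, w, inner),
              conv_params(1, c, inner, cv.conv_bias))
        tr, nt = bn_params(inner)
        t.add(f"{idx}/bn2", block, "bn", None, 1, (h, w, inner), tr, nt)
        t.add(f"{idx}/relu2", block, "relu", None, 1, (h, w, inner))
        if cv.combine == "concatenate":
            t.add(f"{idx}/conv2", block, "conv", (3, 3), 1, (h, w, c),
                  conv_params(3, inner, c, cv.conv_bias))
            t.add(f"{idx}/concat", block, "concat", None, 1, (h, w, 2 * c))
        else:  # projected_add: 1x1-projected shortcut, conv path widened to 2C
            t.add(f"{idx}/conv2", block, "conv", (3, 3), 1, (h, w, 2 * c),
                  conv_params(3, inner, 2 * c, cv.conv_bias))
            t.add(f"{idx}/proj", block, "conv", (1, 1), 1, (h, w, 2 * c),
                  conv_params(1, c, 2 * c, cv.conv_bias), in_shape=(h, w, c))
            t.add(f"{idx}/add", block, "add", None, 1, (h, w, 2 * c))

    skip_channels: list[int] = []
    for lv in range(1, levels + 1):
        cout = base_filters if lv == 1 else t.shape[2]
        transition(f"transition{lv}", f"Transition Block {lv}", cout)
        skip_channels.append(t.shape[2])
        residual(f"residual{lv}", f"Residual Block {lv}")

    # bottleneck: one more transition + residual, then a 1x1 compress conv
    transition("bottleneck/transition", "Bottleneck (transition)", t.shape[2])
    residual("bottleneck/residual", "Bottleneck (residual)")
    h, w, c = t.shape
    compress_out = 2 * base_filters
    if cv.compress_bn:
        tr, nt = bn_params(c)
        t.add("compress/bn", "Bottleneck (compress)", "bn", None, 1, (h, w, c), tr, nt)
    t.add("compress/relu", "Bottleneck (compress)", "relu", None, 1, (h, w, c))
    t.add("compress/conv", "Bottleneck (compress)", "conv", (1, 1), 1, (h, w, compress_out),
          conv_params(1, c, compress_out, cv.conv_bias))
    t.add("compress/dropout", "Bottleneck (compress)", "dropout", None, 1, t.shape)

    for j, lv in enumerate(range(levels, 0, -1), start=1):
        h, w, c = t.shape
        t.add(f"decoder{j}/up", f"Upsampling {j}", "upsample", (2, 2), 2, (2 * h, 2 * w, c))
        h, w, c = t.shape
        skip = skip_channels[lv - 1]
        t.add(f"decoder{j}/concat", f"Concatenate {j}", "concat", None, 1, (h, w, c + skip))
        cout = skip if lv > 1 else 2 * base_filters
        t.add(f"decoder{j}/conv", f"Conv {j}", "conv", (3, 3), 1, (h, w, cout),
              conv_params(3, t.shape[2], cout, cv.conv_bias))
        t.add(f"decoder{j}/relu", f"Conv {j}", "relu", None, 1, t.shape)

    # final refinement conv, last upsampling, 1x1 sigmoid head — the published
    # table names both of the last conv rows "Conv 5"/"Conv5", kept literally
    h, w, c = t.shape
    t.add("head/conv", "Conv 5", "conv", (3, 3), 1, (h, w, base_filters),
          conv_params(3, c, base_filters, cv.conv_bias))
    t.add("head/relu", "Conv 5", "relu", None, 1, t.shape)
    h, w, c = t.shape
    t.add(f"decoder{levels + 1}/up", f"Upsampling {levels + 1}", "upsample", (2, 2), 2,
          (2 * h, 2 * w, c))
    h, w, c = t.shape
    t.add("head/conv_out", "Conv5", "conv", (1, 1), 1, (h, w, 1),
          conv_params(1, c, 1, cv.conv_bias))
    t.add("head/sigmoid", "Conv5", "sigmoid", None, 1, t.shape)
    t.add("output", "Output", "output", None, 1, t.shape)
    return ModelSpec("cnnres", t.records)


def unet_spec(input_size: int = 160) -> ModelSpec:
    """Layer table for the pinned reference U-Net.

    Topology of the widely circulated community implementation: two biased
    3x3 convolutions per level over the 64-128-256-512 ladder, a 1024-wide
    bridge, upsample + 2x2 "up-convolution" decoders, a 2-filter penultimate
    3x3 convolution and a 1-filter 1x1 sigmoid output; no normalisation
    layers anywhere.
    """
    if input_size % 16 != 0:
        raise ArchitectureError(f"input size {input_size} must be divisible by 16")
    t = _Table(input_size, input_size, 1)
    t.add("input", "Input", "input", None, 1, t.shape)
    ladder = [64, 128, 256, 512]

    def double_conv(idx: str, block: str, cout: int):
        for i in (1, 2):
            h, w, c = t.shape
            t.add(f"{idx}/conv{i}", block, "conv", (3, 3), 1, (h, w, cout),
                  conv_params(3, c, cout, True))
            t.add(f"{idx}/relu{i}", block, "relu", None, 1, t.shape)

    for lv, cout in enumerate(ladder, start=1):
        double_conv(f"enc{lv}", f"Encoder {lv}", cout)
        if lv == 4:
            t.add("enc4/dropout", "Encoder 4", "dropout", None, 1, t.shape)
        h, w, c = t.shape
        t.add(f"enc{lv}/pool", f"Encoder {lv}", "maxpool", (2, 2), 2, (h // 2, w // 2, c))

    double_conv("bridge", "Bridge", 1024)
    t.add("bridge/dropout", "Bridge", "dropout", None, 1, t.shape)

    for j, skip in enumerate(reversed(ladder), start=1):
        h, w, c = t.shape
        t.add(f"dec{j}/up", f"Decoder {j}", "upsample", (2, 2), 2, (2 * h, 2 * w, c))
        h, w, c = t.shape
        t.add(f"dec{j}/upconv", f"Decoder {j}", "conv", (2, 2), 1, (h, w, skip),
              conv_params(2, c, skip, True))
        t.add(f"dec{j}/uprelu", f"Decoder {j}", "relu", None, 1, t.shape)
        h, w, c = t.shape
        t.add(f"dec{j}/concat", f"Decoder {j}", "concat", None, 1, (h, w, 2 * skip))
        double_conv(f"dec{j}", f"Decoder {j}", skip)

    h, w, c = t.shape
    t.add("head/conv2ch", "Head", "conv", (3, 3), 1, (h, w, 2), conv_params(3, c, 2, True))
    t.add("head/relu", "Head", "relu", None, 1, t.shape)
    t.add("head/conv_out", "Head", "conv", (1, 1), 1, (h, w, 1), conv_params(1, 2, 1, True))
    t.add("head/sigmoid", "Head", "sigmoid", None, 1, t.shape)
    t.add("output", "Output", "output", None, 1, t.shape)
    return ModelSpec("unet", t.records)


def default_convention_space() -> list[BlockConvention]:
    """The enumerated space of table-consistent block conventions."""
    out = []
    for combine in COMBINE_MODES:
        for wf in (0.5, 1.0, 2.0):
            for compress_bn in (False, True):
                for bias in (True, False):
                    out.append(BlockConvention(combine=combine, width_factor=wf,
                                               compress_bn=compress_bn, conv_bias=bias))
    return out


def reconcile_conventions(space: list[BlockConvention] | None = None) -> pd.DataFrame:
    """Closed-form parameter totals for every convention in ``space`` and
    their absolute distance to the published trainable / non-trainable totals.

    ``exact_trainable`` / ``exact_non_trainable`` flag exact agreement. The
    default space is the full enumerated grid; an empty list yields an empty
    report.
    """
    if space is None:
        space = default_convention_space()
    rows = []
    for cv in space:
        spec = cnnres_spec(cv)
        rows.append({
            "combine": cv.combine,
            "width_factor": cv.width_factor,
            "compress_bn": cv.compress_bn,
            "conv_bias": cv.conv_bias,
            "trainable": spec.trainable,
            "non_trainable": spec.non_trainable,
            "total": spec.total,
            "dist_trainable": abs(spec.trainable - PUBLISHED_TRAINABLE),
            "dist_non_trainable": abs(spec.non_trainable - PUBLISHED_NON_TRAINABLE),
            "exact_trainable": spec.trainable == PUBLISHED_TRAINABLE,
            "exact_non_trainable": spec.non_trainable == PUBLISHED_NON_TRAINABLE,
        })
    cols = ["combine", "width_factor", "compress_bn", "conv_bias", "trainable",
            "non_trainable", "total", "dist_trainable", "dist_non_trainable",
            "exact_trainable", "exact_non_trainable"]
    return pd.DataFrame(rows, columns=cols)


def render_reconciliation(report: pd.DataFrame) -> str:
    """Human-readable reconciliation ledger."""
    lines = [
        "Convention reconciliation against published parameter totals",
        f"published trainable: {PUBLISHED_TRAINABLE:,}   "
        f"published non-trainable: {PUBLISHED_NON_TRAINABLE:,}",
        "",
        report.to_string(index=False) if len(report) else "(empty search space)",
    ]
    if len(report):
        exact_nt = report[report.exact_non_trainable]
        exact_tr = report[report.exact_trainable]
        lines.append("")
        lines.append(f"conventions matching non-trainable total exactly: {len(exact_nt)}")
        if len(exact_tr) == 0:
            lines.append(
                "no enumerated convention reproduces the published trainable total; "
                "closest distance is "
                f"{report.dist_trainable.min():,} parameters")
    return "\n".join(lines)
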