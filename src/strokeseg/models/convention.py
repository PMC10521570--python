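"""Free choices the published layer table leaves open in the residual blocks.

The layer table fixes every output shape but not how the residual (identity)
path is merged with the convolutional path, how wide the 1x1 depth-adjusting
convolution is, whether the bottleneck compress step keeps its normalisation
layer, or whether convolutions carry biases. ``BlockConvention`` enumerates
those choices so a model can be built — and its parameter budget audited —
under any of them.

In the default convention the two paths are merged by channel-wise
concatenation (the table's channel doubling, e.g. 32 in / 64 out, is
impossible for an identity addition), the 1x1 convolution is as wide as the
block input, the compress step carries no normalisation, and convolutions
are biased. Width factor 1.0 and no compress-step normalisation are the
unique choices in the enumerated space that reproduce the published
non-trainable parameter total of 5,952 (bias usage and combine mode do not
affect that total; see :func:`strokeseg.models.spec.reconcile_conventions`).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

COMBINE_MODES = ("concatenate", "projected_add")


@dataclass(frozen=True)
class BlockConvention:
    combine: str = "concatenate"
    width_factor: float = 1.0
    compress_bn: bool = False
    conv_bias: bool = True
    bn_epsilon: float = 1e-3
    bn_momentum: float = 0.99

    def __post_init__(self):
        if self.combine not in COMBINE_MODES:
            raise ValueError(f"combine must be one of {COMBINE_MODES}, got {self.combine!r}")
        if self.width_factor <= 0:
            raise ValueError("width_factor must be positive")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be positive")
        if not 0.0 <= self.bn_momentum < 1.0:
            raise ValueError("bn_momentum must be in [0, 1)")

    def inner_width(self, channels: int) -> int:
        """Output channels of the 1x1 convolution for a block with this input width."""
        w = self.width_factor * channels
        if abs(w - round(w)) > 1e-9:
            raise ValueError(
                f"width_factor {self.width_factor} x {channels} input channels "
                "is not a whole number of channels")
        return int(round(w))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BlockConvention":
        return cls(**d)


DEFAULT_CONVENTION = BlockConvention()
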