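"""Reference U-Net baseline, pinned to the community implementation the
comparison was run against: 64-128-256-512 encoder ladder with two biased
3x3 convolutions per level, a 1024-wide bridge, upsample + 2x2
"up-convolution" decoders, a 2-filter penultimate 3x3 convolution and a
1-filter 1x1 sigmoid output; dropout after encoder level 4 and the bridge;
no normalisation layers, hence zero non-trainable parameters."""

from __future__ import annotations

import numpy as np

from ..errors import ArchitectureError, ShapeError
from ..nn import Conv2D, Dropout, MaxPool2x2, ReLU, Sigmoid, Upsample2x
from .base import Network
from .spec import ModelSpec, unet_spec

LADDER = (64, 128, 256, 512)
BRIDGE = 1024


class UNet(Network):
    def __init__(self, input_size: int = 160, *, dropout_rate: float = 0.5,
                 seed: int | None = 0):
        if input_size % 16 != 0:
            raise ArchitectureError(
                f"input size {input_size} must be divisible by 16 (four pooling stages)")
        super().__init__(seed)
        self.input_size = input_size
        self.spec: ModelSpec = unet_spec(input_size)
        reg = self._register

        def double_conv(idx, cin, cout):
            return {
                "conv1": reg(f"{idx}/conv1", Conv2D(cin, cout, 3, rng=self.rng)),
                "relu1": reg(f"{idx}/relu1", ReLU()),
                "conv2": reg(f"{idx}/conv2", Conv2D(cout, cout, 3, rng=self.rng)),
                "relu2": reg(f"{idx}/relu2", ReLU()),
            }

        self.enc = []
        cin = 1
        for lv, cout in enumerate(LADDER, start=1):
            blk = double_conv(f"enc{lv}", cin, cout)
            if lv == 4:
                blk["dropout"] = reg("enc4/dropout", Dropout(dropout_rate, rng=self.rng))
            blk["pool"] = reg(f"enc{lv}/pool", MaxPool2x2())
            self.enc.append(blk)
            cin = cout

        self.bridge = double_conv("bridge", cin, BRIDGE)
        self.bridge["dropout"] = reg("bridge/dropout", Dropout(dropout_rate, rng=self.rng))

        self.dec = []
        cin = BRIDGE
        for j, skip in enumerate(reversed(LADDER), start=1):
            blk = {
                "up": reg(f"dec{j}/up", Upsample2x()),
                "upconv": reg(f"dec{j}/upconv", Conv2D(cin, skip, 2, rng=self.rng)),
                "uprelu": reg(f"dec{j}/uprelu", ReLU()),
                "skip_ch": skip,
            }
            blk.update(double_conv(f"dec{j}", 2 * skip, skip))
            self.dec.append(blk)
            cin = skip

        self.head_conv = reg("head/conv2ch", Conv2D(cin, 2, 3, rng=self.rng))
        self.head_relu = reg("head/relu", ReLU())
        self.head_out = reg("head/conv_out", Conv2D(2, 1, 1, rng=self.rng))
        self.head_sigmoid = reg("head/sigmoid", Sigmoid())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] % 16 or x.shape[2] % 16 or x.shape[3] != 1:
            raise ShapeError(f"expected (B, H, W, 1) with H, W divisible by 16, got {x.shape}")
        h = np.asarray(x, dtype=np.float32)
        self._skips = []
        for blk in self.enc:
            h = blk["relu1"].forward(blk["conv1"].forward(h, training), training)
            h = blk["relu2"].forward(blk["conv2"].forward(h, training), training)
            if "dropout" in blk:
                h = blk["dropout"].forward(h, training)
            self._skips.append(h)
            h = blk["pool"].forward(h, training)
        h = self.bridge["relu1"].forward(self.bridge["conv1"].forward(h, training), training)
        h = self.bridge["relu2"].forward(self.bridge["conv2"].forward(h, training), training)
        h = self.bridge["dropout"].forward(h, training)
        for j, blk in enumerate(self.dec):
            h = blk["up"].forward(h, training)
            h = blk["uprelu"].forward(blk["upconv"].forward(h, training), training)
            h = np.concatenate([self._skips[3 - j], h], axis=-1)
            h = blk["relu1"].forward(blk["conv1"].forward(h, training), training)
            h = blk["relu2"].forward(blk["conv2"].forward(h, training), training)
        h = self.head_relu.forward(self.head_conv.forward(h, training), training)
        h = self.head_out.forward(h, training)
        return self.head_sigmoid.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head_sigmoid.backward(dout)
        d = self.head_out.backward(d)
        d = self.head_conv.backward(self.head_relu.backward(d))
        dskips = [None] * 4
        for j in range(3, -1, -1):
            blk = self.dec[j]
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))))
            skip_ch = blk["skip_ch"]
            dskips[3 - j] = d[..., :skip_ch]
            d = blk["up"].backward(blk["upconv"].backward(blk["uprelu"].backward(
                d[..., skip_ch:])))
        d = self.bridge["dropout"].backward(d)
        d = self.bridge["conv1"].backward(self.bridge["relu1"].backward(
            self.bridge["conv2"].backward(self.bridge["relu2"].backward(d))))
        for lv in range(3, -1, -1):
            blk = self.enc[lv]
            d = blk["pool"].backward(d)
            d = d + dskips[lv]
            if "dropout" in blk:
                d = blk["dropout"].backward(d)
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))))
        return d


def build_unet_baseline(input_size: int = 160, **kwargs) -> tuple[UNet, ModelSpec]:
    model = UNet(input_size, **kwargs)
    return model, model.spec
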