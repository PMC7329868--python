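"""Segmentation backbones: modified U-Net and modified MS-D Net, 2D and 3D.

Both architectures carry the same two modifications relative to their
originals: batch normalisation is replaced by instance normalisation (valid
at batch size 1) and all activations are LeakyReLU with slope 1e-2.  The
U-Net is the classic encoder/decoder with skip connections and 2x in-plane
scaling; the mixed-scale dense (MS-D) net keeps full resolution throughout
and mixes scales with densely connected dilated convolutions instead of
down/upsampling.  3D variants convolve through the slice axis but never
pool it (CT stacks are short and anisotropic through-plane).

Models map an input array (N, in_channels, *spatial) to class logits of the
same spatial shape; ``predict_proba`` applies the voxel-wise softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["ModelSpec", "SegmentationNet", "UNet", "MSDNet", "build_model"]


@dataclass
class ModelSpec:
    """Configuration of a segmentation backbone.

    ``depth_or_layers`` is the number of 2x scaling levels for the U-Net or
    the number of dense layers for the MS-D net.  ``dilation_schedule``
    (MS-D only) is cycled over layers.
    """

    family: str = "unet"
    dims: int = 2
    in_channels: int = 1
    num_classes: int = 3
    depth_or_layers: int | None = None
    base_width: int | None = None
    dilation_schedule: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 11)))
    leaky_slope: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("unet", "msd"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.depth_or_layers is None:
            self.depth_or_layers = 4 if self.family == "unet" else 40
        if self.base_width is None:
            self.base_width = 24 if self.family == "unet" else 1
        if self.depth_or_layers < 1 or self.base_width < 1:
            raise ValueError("depth/layers and width must be >= 1")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValueError("dilations must be >= 1")
        if self.family == "unet" and tuple(self.dilation_schedule) != tuple(range(1, 11)):
            raise ValueError("dilation_schedule applies to the msd family only")


class SegmentationNet:
    """Common surface of the backbones: logits forward, gradient backward."""

    spec: ModelSpec

    def params(self) -> list[nn.Param]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(np.asarray(x, dtype=np.float64)), axis=1)

    def num_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class _ConvBlock:
    """conv -> instance norm -> LeakyReLU, twice."""

    def __init__(self, in_ch, out_ch, dims, slope, rng):
        self.layers = []
        for i, (ci, co) in enumerate([(in_ch, out_ch), (out_ch, out_ch)]):
            self.layers += [
                nn.Conv(ci, co, dims, 3, rng=rng),
                nn.InstanceNorm(co),
                nn.LeakyReLU(slope),
            ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet(SegmentationNet):
    """Encoder/decoder with skip connections (instance norm + LeakyReLU)."""

    def __init__(self, spec: ModelSpec):
        if spec.family != "unet":
            raise ValueError("spec.family must be 'unet'")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d, w, dims, slope = spec.depth_or_layers, spec.base_width, spec.dims, spec.leaky_slope
        widths = [w * 2**l for l in range(d + 1)]
        self.enc = []
        ch = spec.in_channels
        for l in range(d):
            self.enc.append(_ConvBlock(ch, widths[l], dims, slope, rng))
            ch = widths[l]
        self.pools = [nn.MaxPool2x2() for _ in range(d)]
        self.bottleneck = _ConvBlock(ch, widths[d], dims, slope, rng)
        self.ups = [nn.Upsample2x() for _ in range(d)]
        self.dec = []
        ch = widths[d]
        for l in reversed(range(d)):
            self.dec.append(_ConvBlock(ch + widths[l], widths[l], dims, slope, rng))
            ch = widths[l]
        self.head = nn.Conv(ch, spec.num_classes, dims, 1, rng=rng)

    def params(self):
        ps = []
        for b in self.enc + [self.bottleneck] + self.dec:
            ps += b.params()
        return ps + self.head.params()

    def forward(self, x):
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = block.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits):
        dy = self.head.backward(dlogits)
        dskips = []
        for up, block, sc in zip(reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)):
            dcat = block.backward(dy)
            dskips.append(dcat[:, :sc])
            dy = up.backward(dcat[:, sc:])
        dy = self.bottleneck.backward(dy)
        # dskips was filled shallowest-first; the encoder walks deepest-first
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = block.backward(dy)
        return dy


class MSDNet(SegmentationNet):
    """Mixed-scale dense network: dilated convs, dense connectivity, no scaling."""

    def __init__(self, spec: ModelSpec):
        if spec.family != "msd":
            raise ValueError("spec.family must be 'msd'")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        L, w, dims, slope = spec.depth_or_layers, spec.base_width, spec.dims, spec.leaky_slope
        sched = spec.dilation_schedule
        self.layers = []
        ch = spec.in_channels
        for i in range(L):
            dil = sched[i % len(sched)]
            self.layers.append(
                (nn.Conv(ch, w, dims, 3, dilation=dil, rng=rng), nn.InstanceNorm(w), nn.LeakyReLU(slope))
            )
            ch += w
        self.head = nn.Conv(ch, spec.num_classes, dims, 1, rng=rng)

    def params(self):
        ps = []
        for conv, norm, _ in self.layers:
            ps += conv.params() + norm.params()
        return ps + self.head.params()

    def forward(self, x):
        feats = [x]
        for conv, norm, act in self.layers:
            inp = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(act.forward(norm.forward(conv.forward(inp))))
        self._widths = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, dlogits):
        widths = self._widths
        dcat = self.head.backward(dlogits)
        splits = np.cumsum(widths)[:-1]
        dfeats = list(np.split(dcat, splits, axis=1))
        for i in reversed(range(len(self.layers))):
            conv, norm, act = self.layers[i]
            dinp = conv.backward(norm.backward(act.backward(dfeats[i + 1])))
            dparts = np.split(dinp, np.cumsum(widths[: i + 1])[:-1], axis=1)
            for j, dp in enumerate(dparts):
                dfeats[j] = dfeats[j] + dp
        return dfeats[0]


def build_model(spec: ModelSpec) -> SegmentationNet:
    """Instantiate a backbone from its spec; same (spec, seed) gives identical
    initial parameters."""
    if spec.family == "unet":
        return UNet(spec)
    return MSDNet(spec)
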