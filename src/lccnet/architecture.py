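"""Network architectures: Ghost convolution block, U-Net backbone (standard
or lightweight "L-Unet" variant), and the shared-encoder / three-decoder
cross-consistency assembly.

The Ghost module generates an output of ``b`` channels from ``a`` input
channels in two stages: a standard 3x3 convolution compresses the input to
``b/s`` *primary* channels, and ``s - 1`` cheap per-channel (depthwise) 3x3
convolutions each derive another ``b/s`` "ghost" maps from the primary ones.
Together with the identity copy of the primary maps this yields ``b``
channels at roughly ``1/s`` of the parameter cost of a standard ``a -> b``
convolution.

The cross-consistency assembly shares one encoder ``E`` among three
architecturally identical but independently parameterized decoders: the
supervised decoder ``D_S`` and two auxiliary decoders ``D_D`` (spatial
dropout on the bottleneck features) and ``D_N`` (Gaussian noise on the
bottleneck features).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Module,
    Conv2d,
    DepthwiseConv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    ReLU,
    BilinearUp2d,
    MaxPool2d,
    Softmax2d,
)
from .perturbations import FeaturePerturbConfig, feature_dropout, feature_noise

__all__ = [
    "GhostConfig",
    "BackboneConfig",
    "GhostModule",
    "ConvUnit",
    "UNet",
    "LCCNetAssembly",
    "build_backbone",
    "build_lccnet",
    "forward_paths",
]


@dataclass(frozen=True)
class GhostConfig:
    """Configuration of one Ghost block mapping ``in_channels -> out_channels``."""

    in_channels: int
    out_channels: int
    ratio: int = 4
    primary_kernel: int = 3
    cheap_kernel: int = 3
    use_norm_act: bool = True
    bias: bool = True

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.ratio < 1:
            raise ValueError("ghost ratio s must be >= 1")
        if self.out_channels % self.ratio:
            raise ValueError(
                f"out_channels={self.out_channels} not divisible by ratio s={self.ratio}"
            )
        if self.primary_kernel != 3 or self.cheap_kernel != 3:
            raise ValueError("only 3x3 primary/cheap kernels are supported")


# Decoder mid-widths of the full-scale model, frozen once so that the
# standard-convolution network reproduces the reference complexity figures
# (35.5 M test-time / 81.5 M training-time parameters); see docs/methods.md.
PAPER_SCALE_BASE_WIDTH = 52
PAPER_SCALE_DECODER_MIDS = (1152, 584, 296, 148)


@dataclass(frozen=True)
class BackboneConfig:
    """Configuration of the segmentation backbone.

    ``depth`` resolution levels with channel widths doubling from
    ``base_width``; the decoder mirrors the encoder through skip connections.
    ``decoder_mid_channels`` optionally fixes the width of the first conv of
    each decoder block (deepest level first); by default it equals the block's
    output width.
    """

    depth: int = 5
    base_width: int = PAPER_SCALE_BASE_WIDTH
    in_channels: int = 1
    num_classes: int = 4
    block_kind: str = "standard"
    upsample_kind: str = "bilinear"
    ghost_ratio: int = 4
    use_norm: bool = True
    bias: bool = True
    decoder_mid_channels: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        if self.block_kind not in ("standard", "ghost"):
            raise ValueError(f"unknown block_kind {self.block_kind!r}")
        if self.upsample_kind not in ("transposed_conv", "bilinear"):
            raise ValueError(f"unknown upsample_kind {self.upsample_kind!r}")
        if self.decoder_mid_channels is not None and len(self.decoder_mid_channels) != self.depth - 1:
            raise ValueError("decoder_mid_channels must have depth-1 entries")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**i for i in range(self.depth))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        if d.get("decoder_mid_channels") is not None:
            d["decoder_mid_channels"] = tuple(d["decoder_mid_channels"])
        return cls(**d)

    @classmethod
    def paper_scale(cls, block_kind: str = "standard") -> "BackboneConfig":
        """The frozen full-scale configuration (160x160 inputs)."""
        return cls(
            depth=5,
            base_width=PAPER_SCALE_BASE_WIDTH,
            block_kind=block_kind,
            decoder_mid_channels=PAPER_SCALE_DECODER_MIDS,
        )

    @classmethod
    def tiny(cls, block_kind: str = "ghost", depth: int = 3, base_width: int = 8) -> "BackboneConfig":
        """A desk-scale configuration for 64x64 phantom experiments."""
        return cls(depth=depth, base_width=base_width, block_kind=block_kind)


class ConvUnit(Module):
    """Standard 3x3 convolution followed (optionally) by instance norm + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng,
                 use_norm_act: bool = True, bias: bool = True):
        self.conv = Conv2d(in_channels, out_channels, 3, bias=bias, rng=rng)
        self.use_norm_act = use_norm_act
        if use_norm_act:
            self.norm = InstanceNorm2d(out_channels)
            self.act = ReLU()

    def forward(self, x):
        y = self.conv(x)
        if self.use_norm_act:
            y = self.act(self.norm(y))
        return y

    def backward(self, dy):
        if self.use_norm_act:
            dy = self.norm.backward(self.act.backward(dy))
        return self.conv.backward(dy)


class GhostModule(Module):
    """Ghost block: primary compression conv + cheap depthwise ghost maps.

    The first ``b/s`` output channels are exactly the primary feature map
    (the identity group); the remaining ``(s-1) * b/s`` channels are cheap
    depthwise transforms of it. With ``s = 1`` the block degenerates to a
    single standard convolution.
    """

    def __init__(self, cfg: GhostConfig, rng):
        self.cfg = cfg
        prim = cfg.out_channels // cfg.ratio
        self.primary = ConvUnit(cfg.in_channels, prim, rng,
                                use_norm_act=cfg.use_norm_act, bias=cfg.bias)
        self.cheap = []
        for _ in range(cfg.ratio - 1):
            branch = {"dw": DepthwiseConv2d(prim, bias=cfg.bias, rng=rng)}
            if cfg.use_norm_act:
                branch["norm"] = InstanceNorm2d(prim)
                branch["act"] = ReLU()
            self.cheap.append(branch)
        # expose branch modules for parameter discovery
        self._cheap_modules = [m for br in self.cheap for m in br.values()]

    def forward(self, x):
        fprime = self.primary(x)
        groups = [fprime]
        for br in self.cheap:
            g = br["dw"](fprime)
            if "norm" in br:
                g = br["act"](br["norm"](g))
            groups.append(g)
        self._prim_channels = fprime.shape[1]
        return np.concatenate(groups, axis=1)

    def backward(self, dy):
        prim = self._prim_channels
        dfprime = dy[:, :prim].copy()
        for k, br in enumerate(self.cheap):
            dg = dy[:, (k + 1) * prim : (k + 2) * prim]
            if "norm" in br:
                dg = br["norm"].backward(br["act"].backward(dg))
            dfprime += br["dw"].backward(dg)
        return self.primary.backward(dfprime)


def _make_unit(kind: str, in_ch: int, out_ch: int, cfg: BackboneConfig, rng) -> Module:
    if kind == "ghost":
        return GhostModule(
            GhostConfig(in_ch, out_ch, ratio=cfg.ghost_ratio,
                        use_norm_act=cfg.use_norm, bias=cfg.bias),
            rng,
        )
    return ConvUnit(in_ch, out_ch, rng, use_norm_act=cfg.use_norm, bias=cfg.bias)


class _DoubleBlock(Module):
    """Two convolution units (standard or ghost) in sequence."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, cfg: BackboneConfig, rng):
        self.unit1 = _make_unit(cfg.block_kind, in_ch, mid_ch, cfg, rng)
        self.unit2 = _make_unit(cfg.block_kind, mid_ch, out_ch, cfg, rng)

    def forward(self, x):
        return self.unit2(self.unit1(x))

    def backward(self, dy):
        return self.unit1.backward(self.unit2.backward(dy))


class Encoder(Module):
    """Contracting path; returns skip features and the bottleneck feature."""

    def __init__(self, cfg: BackboneConfig, rng):
        self.cfg = cfg
        widths = cfg.widths
        self.blocks = []
        self.pools = []
        in_ch = cfg.in_channels
        for lvl, w in enumerate(widths):
            self.blocks.append(_DoubleBlock(in_ch, w, w, cfg, rng))
            if lvl < cfg.depth - 1:
                self.pools.append(MaxPool2d())
            in_ch = w

    def forward(self, x):
        skips = []
        h = x
        for lvl, block in enumerate(self.blocks):
            h = block(h)
            if lvl < self.cfg.depth - 1:
                skips.append(h)
                h = self.pools[lvl](h)
        return skips, h

    def backward(self, d_bottom, d_skips):
        dh = d_bottom
        for lvl in range(self.cfg.depth - 1, -1, -1):
            if lvl < self.cfg.depth - 1:
                dh = self.pools[lvl].backward(dh)
                dh = dh + d_skips[lvl]
            dh = self.blocks[lvl].backward(dh)
        return dh


class Decoder(Module):
    """Expanding path with skip connections, 1x1 classifier and softmax."""

    def __init__(self, cfg: BackboneConfig, rng):
        self.cfg = cfg
        widths = cfg.widths
        self.ups = []
        self.blocks = []
        below = widths[-1]
        mids = cfg.decoder_mid_channels
        for i, lvl in enumerate(range(cfg.depth - 2, -1, -1)):
            skip = widths[lvl]
            if cfg.upsample_kind == "bilinear":
                self.ups.append(BilinearUp2d())
                up_ch = below
            else:
                self.ups.append(ConvTranspose2d(below, skip, bias=cfg.bias, rng=rng))
                up_ch = skip
            cat = up_ch + skip
            mid = mids[i] if mids is not None else skip
            self.blocks.append(_DoubleBlock(cat, mid, skip, cfg, rng))
            below = skip
        self.classifier = Conv2d(widths[0], cfg.num_classes, 1, bias=True, rng=rng)
        self.softmax = Softmax2d()

    def forward(self, bottom, skips):
        self._split = []
        h = bottom
        for i, lvl in enumerate(range(self.cfg.depth - 2, -1, -1)):
            up = self.ups[i](h)
            skip = skips[lvl]
            self._split.append(up.shape[1])
            h = self.blocks[i](np.concatenate([up, skip], axis=1))
        logits = self.classifier(h)
        return self.softmax(logits)

    def backward(self, dprobs):
        dlogits = self.softmax.backward(dprobs)
        dh = self.classifier.backward(dlogits)
        d_skips = [None] * (self.cfg.depth - 1)
        for i in range(len(self.blocks) - 1, -1, -1):
            lvl = self.cfg.depth - 2 - i
            dcat = self.blocks[i].backward(dh)
            up_ch = self._split[i]
            d_skips[lvl] = dcat[:, up_ch:]
            dh = self.ups[i].backward(dcat[:, :up_ch].copy())
        return dh, d_skips


class UNet(Module):
    """Encoder-decoder segmentation network mapping an image to a probability map."""

    def __init__(self, cfg: BackboneConfig, encoder: Encoder, decoder: Decoder):
        self.cfg = cfg
        self.encoder = encoder
        self.decoder = decoder

    def _check_input(self, x):
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N,{self.cfg.in_channels},H,W) input, got {x.shape}")
        stride = 2 ** (self.cfg.depth - 1)
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(
                f"spatial size {x.shape[2:]}, must be divisible by {stride} at depth {self.cfg.depth}"
            )

    def forward(self, x):
        self._check_input(x)
        skips, bottom = self.encoder(x)
        return self.decoder(bottom, skips)

    def backward(self, dprobs):
        d_bottom, d_skips = self.decoder.backward(dprobs)
        return self.encoder.backward(d_bottom, d_skips)


class LCCNetAssembly(Module):
    """Shared encoder plus three architecturally identical, independent decoders."""

    def __init__(self, cfg: BackboneConfig, encoder: Encoder,
                 dec_s: Decoder, dec_d: Decoder, dec_n: Decoder,
                 perturb: FeaturePerturbConfig | None = None):
        self.cfg = cfg
        self.encoder = encoder
        self.dec_s = dec_s
        self.dec_d = dec_d
        self.dec_n = dec_n
        self.perturb = perturb if perturb is not None else FeaturePerturbConfig()

    def segmentation_network(self) -> UNet:
        """The test-time network ``f_S = D_S o E`` (shares weights)."""
        return UNet(self.cfg, self.encoder, self.dec_s)

    def forward(self, x):
        return self.segmentation_network().forward(x)


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> UNet:
    """Build a single encoder-decoder segmentation network.

    Weight initialization is deterministic in ``seed``; the encoder and
    decoder draw from streams shared with :func:`build_lccnet`, so the
    backbone equals the assembly's test-time network at the same seed.
    """
    encoder = Encoder(cfg, _rng_for(seed, 0))
    decoder = Decoder(cfg, _rng_for(seed, 1))
    return UNet(cfg, encoder, decoder)


def build_lccnet(cfg: BackboneConfig, seed: int = 0,
                 perturb: FeaturePerturbConfig | None = None) -> LCCNetAssembly:
    """Build the cross-consistency assembly (one encoder, three decoders)."""
    encoder = Encoder(cfg, _rng_for(seed, 0))
    dec_s = Decoder(cfg, _rng_for(seed, 1))
    dec_d = Decoder(cfg, _rng_for(seed, 2))
    dec_n = Decoder(cfg, _rng_for(seed, 3))
    return LCCNetAssembly(cfg, encoder, dec_s, dec_d, dec_n, perturb)


def forward_paths(net: LCCNetAssembly, x: np.ndarray, seed: int = 0):
    """Run the three prediction paths ``f_S``, ``f_D``, ``f_N`` on a batch.

    ``f_S`` decodes the clean bottleneck feature; ``f_D`` decodes after
    spatial dropout and ``f_N`` after additive Gaussian noise. Skip features
    are passed to the auxiliary decoders unperturbed. Deterministic in
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 100]))
    skips, h = net.encoder(x)
    p_s = net.dec_s(h, skips)
    h_d, _ = feature_dropout(h, net.perturb.dropout_range, rng)
    p_d = net.dec_d(h_d, skips)
    h_n = feature_noise(h, net.perturb.noise_sigma, rng)
    p_n = net.dec_n(h_n, skips)
    return p_s, p_d, p_n
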