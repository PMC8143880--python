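"""Model complexity accounting: trainable parameter counts and FLOPs.

FLOP convention: one multiply-accumulate = 2 FLOPs, counted over
convolutional layers (standard, depthwise and transposed) for a single
forward pass at the stated input shape. Normalization, activations, pooling,
interpolation and bias additions are excluded. Because conventions vary,
absolute FLOPs are reported with this tag and cross-architecture
comparisons should use ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .architecture import (
    BackboneConfig,
    ConvUnit,
    Decoder,
    Encoder,
    GhostModule,
    LCCNetAssembly,
    UNet,
    _DoubleBlock,
    build_lccnet,
)
from .nn import (
    BilinearUp2d,
    Conv2d,
    ConvTranspose2d,
    DepthwiseConv2d,
    InstanceNorm2d,
    MaxPool2d,
    ReLU,
    Softmax2d,
)

__all__ = ["count_params", "count_flops", "complexity_report", "ComplexityReport"]

FLOP_CONVENTION = "2 FLOPs per MAC; conv/depthwise/transposed-conv only"


def count_params(network) -> int:
    """Exact number of trainable weight elements of a built network."""
    return network.num_params()


def _macs(module, shape):
    """(MAC count, output shape) of a module applied at (C, H, W)."""
    C, H, W = shape
    if isinstance(module, Conv2d):
        k = module.kernel_size
        return k * k * module.in_channels * module.out_channels * H * W, (
            module.out_channels, H, W)
    if isinstance(module, DepthwiseConv2d):
        return 9 * module.channels * H * W, (module.channels, H, W)
    if isinstance(module, ConvTranspose2d):
        return 4 * module.in_channels * module.out_channels * H * W, (
            module.out_channels, 2 * H, 2 * W)
    if isinstance(module, (InstanceNorm2d, ReLU, Softmax2d)):
        return 0, shape
    if isinstance(module, MaxPool2d):
        return 0, (C, H // 2, W // 2)
    if isinstance(module, BilinearUp2d):
        return 0, (C, 2 * H, 2 * W)
    if isinstance(module, ConvUnit):
        total, shape = _macs(module.conv, shape)
        return total, shape
    if isinstance(module, GhostModule):
        total, pshape = _macs(module.primary, shape)
        for br in module.cheap:
            m, _ = _macs(br["dw"], pshape)
            total += m
        pc, ph, pw = pshape
        return total, (pc * module.cfg.ratio, ph, pw)
    if isinstance(module, _DoubleBlock):
        m1, shape = _macs(module.unit1, shape)
        m2, shape = _macs(module.unit2, shape)
        return m1 + m2, shape
    raise TypeError(f"no MAC rule for {type(module).__name__}")


def _encoder_macs(enc: Encoder, shape):
    total = 0
    skips = []
    for lvl, block in enumerate(enc.blocks):
        m, shape = _macs(block, shape)
        total += m
        if lvl < enc.cfg.depth - 1:
            skips.append(shape)
            _, shape = _macs(enc.pools[lvl], shape)
    return total, skips, shape


def _decoder_macs(dec: Decoder, bottom_shape, skip_shapes):
    total = 0
    shape = bottom_shape
    for i, lvl in enumerate(range(dec.cfg.depth - 2, -1, -1)):
        m, up_shape = _macs(dec.ups[i], shape)
        total += m
        sc, sh, sw = skip_shapes[lvl]
        cat_shape = (up_shape[0] + sc, sh, sw)
        m, shape = _macs(dec.blocks[i], cat_shape)
        total += m
    m, shape = _macs(dec.classifier, shape)
    return total + m


def count_flops(network, input_shape) -> int:
    """FLOPs of one forward pass at ``input_shape = (C, H, W)``.

    For an :class:`LCCNetAssembly` this is the training-time cost (encoder
    plus all three decoders); pass ``assembly.segmentation_network()`` for
    the test-time cost.
    """
    C, H, W = input_shape
    if isinstance(network, UNet):
        if C != network.cfg.in_channels:
            raise ValueError(f"expected {network.cfg.in_channels} input channels, got {C}")
        stride = 2 ** (network.cfg.depth - 1)
        if H % stride or W % stride:
            raise ValueError(f"spatial size {(H, W)} not divisible by {stride}")
        enc_macs, skips, bottom = _encoder_macs(network.encoder, input_shape)
        dec_macs = _decoder_macs(network.decoder, bottom, skips)
        return 2 * (enc_macs + dec_macs)
    if isinstance(network, LCCNetAssembly):
        enc_macs, skips, bottom = _encoder_macs(network.encoder, input_shape)
        total = enc_macs
        for dec in (network.dec_s, network.dec_d, network.dec_n):
            total += _decoder_macs(dec, bottom, skips)
        return 2 * total
    raise TypeError(f"cannot count FLOPs of {type(network).__name__}")


@dataclass(frozen=True)
class ComplexityReport:
    """Training-time vs test-time parameters and FLOPs for both block kinds."""

    input_shape: tuple[int, int, int]
    params_train: dict  # block_kind -> int
    params_test: dict
    flops_train: dict
    flops_test: dict
    flop_convention: str = FLOP_CONVENTION

    def as_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "flop_convention": self.flop_convention,
            "rows": {
                kind: {
                    "params_train": self.params_train[kind],
                    "params_train_M": round(self.params_train[kind] / 1e6, 1),
                    "params_test": self.params_test[kind],
                    "params_test_M": round(self.params_test[kind] / 1e6, 1),
                    "flops_train": self.flops_train[kind],
                    "flops_train_G": round(self.flops_train[kind] / 1e9, 1),
                    "flops_test": self.flops_test[kind],
                    "flops_test_G": round(self.flops_test[kind] / 1e9, 1),
                }
                for kind in self.params_train
            },
        }

    def as_text(self) -> str:
        lines = [
            f"input {self.input_shape}; convention: {self.flop_convention}",
            f"{'block kind':<22}{'params train':>14}{'params test':>14}"
            f"{'FLOPs train':>14}{'FLOPs test':>14}",
        ]
        for kind in self.params_train:
            lines.append(
                f"{kind:<22}"
                f"{self.params_train[kind] / 1e6:>12.1f} M"
                f"{self.params_test[kind] / 1e6:>12.1f} M"
                f"{self.flops_train[kind] / 1e9:>12.1f} G"
                f"{self.flops_test[kind] / 1e9:>12.1f} G"
            )
        return "\n".join(lines)


def complexity_report(cfg: BackboneConfig | None = None,
                      input_shape=(1, 160, 160)) -> ComplexityReport:
    """Tabulate params and FLOPs for standard and ghost variants of a config.

    With no config, the frozen full-scale configuration is used.
    """
    params_train, params_test, flops_train, flops_test = {}, {}, {}, {}
    for kind in ("standard", "ghost"):
        if cfg is None:
            c = BackboneConfig.paper_scale(block_kind=kind)
        else:
            c = BackboneConfig.from_dict({**cfg.to_dict(), "block_kind": kind})
        assembly = build_lccnet(c, seed=0)
        test_net = assembly.segmentation_network()
        params_train[kind] = count_params(assembly)
        params_test[kind] = count_params(test_net)
        flops_train[kind] = count_flops(assembly, input_shape)
        flops_test[kind] = count_flops(test_net, input_shape)
        del assembly, test_net
    return ComplexityReport(
        input_shape=tuple(input_shape),
        params_train=params_train,
        params_test=params_test,
        flops_train=flops_train,
        flops_test=flops_test,
    )
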