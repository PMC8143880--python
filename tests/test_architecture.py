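"""Ghost block and backbone architecture contracts."""

import numpy as np
import pytest

from lccnet.architecture import (
    BackboneConfig,
    ConvUnit,
    GhostConfig,
    GhostModule,
    build_backbone,
    build_lccnet,
    forward_paths,
)
from lccnet.perturbations import FeaturePerturbConfig


def ghost_param_formula(a, b, s, k=3, d=3, bias=True):
    """Independent closed form: primary k x k conv a -> b/s plus (s-1)
    depthwise d x d transforms on b/s channels."""
    prim = k * k * a * (b // s) + (b // s if bias else 0)
    cheap = (s - 1) * (d * d * (b // s) + ((b // s) if bias else 0))
    return prim + cheap


class TestGhostModule:
    def test_param_count_matches_formula_for_random_configs(self, rng):
        for _ in range(20):
            s = int(rng.choice([1, 2, 4]))
            a = int(rng.integers(1, 12))
            b = int(s * rng.integers(1, 12))
            bias = bool(rng.integers(0, 2))
            cfg = GhostConfig(a, b, ratio=s, use_norm_act=False, bias=bias)
            mod = GhostModule(cfg, rng)
            # brute-force enumeration of every weight array
            enumerated = sum(p.data.size for _, p in mod.named_parameters())
            assert enumerated == ghost_param_formula(a, b, s, bias=bias)

    def test_reference_counts(self, rng):
        # 64 -> 64 at s=4, bias-free: 9*64*16 + 3*16*9 = 9648 (vs 36864 standard)
        cfg = GhostConfig(64, 64, ratio=4, use_norm_act=False, bias=False)
        assert GhostModule(cfg, rng).num_params() == 9648
        # s=1 degenerates to a standard conv (bias included)
        cfg1 = GhostConfig(16, 16, ratio=1, use_norm_act=False, bias=True)
        assert GhostModule(cfg1, rng).num_params() == 9 * 16 * 16 + 16

    def test_s1_block_equals_standard_conv_outputs(self, rng):
        ghost = GhostModule(GhostConfig(3, 8, ratio=1), rng)
        conv = ConvUnit(3, 8, np.random.default_rng(5))
        # copy the ghost primary weights into the standard conv unit
        conv.load_state_dict({k[len("primary."):]: v
                              for k, v in ghost.state_dict().items()})
        assert ghost.num_params() == conv.num_params()
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        assert np.array_equal(ghost.forward(x), conv.forward(x))

    def test_identity_group_is_primary_output(self, rng):
        cfg = GhostConfig(5, 12, ratio=4)
        mod = GhostModule(cfg, rng)
        x = rng.normal(size=(1, 5, 6, 6)).astype(np.float32)
        out = mod.forward(x)
        assert out.shape == (1, 12, 6, 6)
        assert np.array_equal(out[:, :3], mod.primary.forward(x))

    def test_zero_weights_give_zero_output(self, rng):
        cfg = GhostConfig(4, 8, ratio=2, use_norm_act=False)
        mod = GhostModule(cfg, rng)
        for p in mod.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        assert np.all(mod.forward(x) == 0.0)
        assert mod.forward(x).shape == (1, 8, 6, 6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            GhostConfig(8, 10, ratio=4)

    def test_channel_mismatch_rejected(self, rng):
        mod = GhostModule(GhostConfig(4, 8, ratio=2), rng)
        with pytest.raises(ValueError, match="channels"):
            mod.forward(np.zeros((1, 3, 6, 6), dtype=np.float32))


def unet_param_formula(cfg: BackboneConfig):
    """Independent layer-by-layer sum for a standard-conv backbone."""

    def conv(a, b, k=3):
        n = k * k * a * b
        if cfg.bias:
            n += b
        if cfg.use_norm and k == 3:
            n += 2 * b
        return n

    widths = cfg.widths
    total = 0
    cin = cfg.in_channels
    for w in widths:  # encoder double conv per level
        total += conv(cin, w) + conv(w, w)
        cin = w
    below = widths[-1]
    mids = cfg.decoder_mid_channels
    for i, lvl in enumerate(range(cfg.depth - 2, -1, -1)):
        skip = widths[lvl]
        if cfg.upsample_kind == "transposed_conv":
            total += 4 * below * skip + (skip if cfg.bias else 0)
            cat = 2 * skip
        else:
            cat = below + skip
        mid = mids[i] if mids is not None else skip
        total += conv(cat, mid) + conv(mid, skip)
        below = skip
    total += widths[0] * cfg.num_classes + cfg.num_classes  # 1x1 classifier
    return total


class TestBackbone:
    @pytest.mark.parametrize("upsample", ["bilinear", "transposed_conv"])
    def test_param_count_matches_analytic_sum(self, upsample):
        cfg = BackboneConfig(depth=3, base_width=4, block_kind="standard",
                             upsample_kind=upsample)
        net = build_backbone(cfg, seed=0)
        assert net.num_params() == unet_param_formula(cfg)

    def test_output_is_probability_map(self, rng):
        cfg = BackboneConfig(depth=3, base_width=4, block_kind="ghost")
        net = build_backbone(cfg, seed=0)
        x = rng.random((2, 1, 16, 16), dtype=np.float32)
        p = net.forward(x)
        assert p.shape == (2, 4, 16, 16)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_invalid_spatial_size_rejected(self, rng):
        net = build_backbone(BackboneConfig(depth=4, base_width=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))


class TestAssembly:
    def test_param_composition_identity(self):
        cfg = BackboneConfig(depth=3, base_width=8, block_kind="ghost")
        asm = build_lccnet(cfg, seed=0)
        enc = asm.encoder.num_params()
        dec = asm.dec_s.num_params()
        assert asm.dec_d.num_params() == dec
        assert asm.dec_n.num_params() == dec
        assert asm.num_params() == enc + 3 * dec
        assert asm.segmentation_network().num_params() == enc + dec

    def test_decoders_have_independent_weights(self):
        asm = build_lccnet(BackboneConfig(depth=2, base_width=4), seed=0)
        w_s = next(asm.dec_s.parameters()).data
        w_d = next(asm.dec_d.parameters()).data
        assert w_s.shape == w_d.shape
        assert not np.array_equal(w_s, w_d)

    def test_backbone_shares_init_with_assembly(self):
        cfg = BackboneConfig(depth=2, base_width=4)
        asm = build_lccnet(cfg, seed=3)
        net = build_backbone(cfg, seed=3)
        for (na, pa), (nb, pb) in zip(
            asm.segmentation_network().named_parameters(), net.named_parameters()
        ):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_forward_paths_deterministic_and_valid(self, rng):
        cfg = BackboneConfig(depth=2, base_width=4)
        asm = build_lccnet(cfg, seed=0)
        x = rng.random((2, 1, 16, 16), dtype=np.float32)
        p1 = forward_paths(asm, x, seed=11)
        p2 = forward_paths(asm, x, seed=11)
        for a, b in zip(p1, p2):
            assert np.array_equal(a, b)
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_perturbation_with_copied_decoders_collapses_paths(self, rng):
        cfg = BackboneConfig(depth=2, base_width=4)
        asm = build_lccnet(cfg, seed=0,
                           perturb=FeaturePerturbConfig(noise_sigma=0.0,
                                                        dropout_range=(0.0, 0.0)))
        state = asm.dec_s.state_dict()
        asm.dec_d.load_state_dict(state)
        asm.dec_n.load_state_dict(state)
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        p_s, p_d, p_n = forward_paths(asm, x, seed=0)
        assert np.array_equal(p_s, p_d)
        assert np.array_equal(p_s, p_n)
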