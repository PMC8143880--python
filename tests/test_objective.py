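"""Loss terms and the consistency-weight ramp-up schedule."""

import math

import numpy as np
import pytest

from lccnet.architecture import BackboneConfig, build_lccnet
from lccnet.nn.losses import cross_entropy_from_probs, mse_consistency
from lccnet.objective import (
    LossReport,
    ScheduleParams,
    consistency_loss,
    lambda_schedule,
    supervised_loss,
    total_loss,
)
from lccnet.perturbations import feature_dropout, feature_noise


class TestSupervisedLoss:
    def test_one_hot_prediction_is_zero(self):
        labels = np.array([[[0, 1], [2, 3]]])
        probs = np.zeros((1, 4, 2, 2), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                probs[0, labels[0, i, j], i, j] = 1.0
        assert supervised_loss(probs, labels) <= 1e-6

    def test_uniform_prediction_is_log_k(self, rng):
        probs = np.full((2, 4, 3, 3), 0.25, dtype=np.float32)
        labels = rng.integers(0, 4, (2, 3, 3))
        assert math.isclose(supervised_loss(probs, labels), math.log(4), rel_tol=1e-6)

    def test_hand_computed_2x2_example(self):
        # probabilities of the true class at the four pixels: .7 .4 .1 .9
        probs = np.zeros((1, 2, 2, 2), dtype=np.float32)
        probs[0, 0] = [[0.7, 0.6], [0.1, 0.9]]
        probs[0, 1] = 1.0 - probs[0, 0]
        labels = np.array([[[0, 1], [0, 0]]])
        expected = -(math.log(0.7) + math.log(0.4) + math.log(0.1) + math.log(0.9)) / 4
        assert math.isclose(supervised_loss(probs, labels), expected, rel_tol=1e-5)

    def test_invalid_labels_rejected(self):
        probs = np.full((1, 4, 2, 2), 0.25, dtype=np.float32)
        with pytest.raises(ValueError):
            supervised_loss(probs, np.full((1, 2, 2), 7))

    def test_list_input_averages_per_slice(self, rng):
        p = np.full((4, 3, 3), 1 / 3, dtype=np.float32)
        y = rng.integers(0, 3, (3, 3))
        single = supervised_loss(p[None][0], y)  # 3D input path
        pair = supervised_loss([p, p], [y, y])
        assert math.isclose(single, pair, rel_tol=1e-6)


class TestConsistencyLoss:
    def test_agreement_is_zero(self, rng):
        p = rng.random((2, 4, 4, 4)).astype(np.float32)
        assert consistency_loss(p, p.copy(), p.copy()) == 0.0

    def test_hand_computed_single_pixel(self):
        p_s = np.array([1.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
        p_d = np.array([0.5, 0.5], dtype=np.float32).reshape(1, 2, 1, 1)
        p_n = p_s.copy()
        # d1 = (0.25 + 0.25) / 2 = 0.25, d2 = 0
        assert math.isclose(consistency_loss(p_s, p_d, p_n), 0.25, rel_tol=1e-6)

    def test_symmetric_in_auxiliary_maps(self, rng):
        p_s = rng.random((1, 3, 4, 4)).astype(np.float32)
        p_d = rng.random((1, 3, 4, 4)).astype(np.float32)
        p_n = rng.random((1, 3, 4, 4)).astype(np.float32)
        assert math.isclose(consistency_loss(p_s, p_d, p_n),
                            consistency_loss(p_s, p_n, p_d), rel_tol=1e-6)

    def test_quadratic_scaling(self, rng):
        p_s = rng.random((1, 3, 4, 4)).astype(np.float32)
        delta = rng.normal(0, 0.1, p_s.shape).astype(np.float32)
        base = consistency_loss(p_s, p_s + delta, p_s.copy())
        scaled = consistency_loss(p_s, p_s + 3 * delta, p_s.copy())
        assert math.isclose(scaled, 9 * base, rel_tol=1e-4)

    def test_shape_mismatch_rejected(self, rng):
        p = rng.random((1, 3, 4, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            consistency_loss(p, p[:, :, :2], p)


class TestLambdaSchedule:
    def test_reference_values(self):
        assert lambda_schedule(ScheduleParams(0.4, 3000, 3000)) == 0.4
        assert lambda_schedule(ScheduleParams(0.4, 3000, 1500)) == pytest.approx(0.4)
        assert lambda_schedule(ScheduleParams(0.4, 3000, 0)) == pytest.approx(0.4 / math.e)

    def test_monotone_bounded_and_capped(self):
        vals = [lambda_schedule(ScheduleParams(0.4, 200, e)) for e in range(0, 401)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0.4 / math.e <= v <= 0.4 + 1e-12 for v in vals)
        # cap reached at stop/2 and held from there on
        assert vals[100] == pytest.approx(0.4)
        assert all(v == pytest.approx(0.4) for v in vals[100:])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScheduleParams(0.4, 0, 0)
        with pytest.raises(ValueError):
            ScheduleParams(-0.1, 10, 0)


class TestTotalLoss:
    def test_identity_and_edge_cases(self):
        rep = total_loss(1.0, 0.5, 0.4)
        assert rep.total == pytest.approx(1.2)
        assert total_loss(1.0, 0.5, 0.0).total == 1.0
        assert total_loss(2.5, 0.0, 0.7).total == 2.5
        assert isinstance(rep, LossReport)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            total_loss(float("nan"), 0.0, 0.4)
        with pytest.raises(FloatingPointError):
            total_loss(0.0, float("inf"), 0.4)


class TestGradientContracts:
    def test_consistency_target_carries_no_gradient(self, rng):
        """The consistency term must not push gradients into the supervised
        decoder: after a consistency-only backward pass, D_S's parameter
        gradients are exactly zero while D_D's and the encoder's are not."""
        asm = build_lccnet(BackboneConfig(depth=2, base_width=4), seed=0)
        x = rng.random((2, 1, 8, 8), dtype=np.float32)
        skips, h = asm.encoder(x)
        p_target = asm.dec_s(h, skips)
        stream = np.random.default_rng(0)
        h_d, keep = feature_dropout(h, (0.1, 0.4), stream)
        p_d = asm.dec_d(h_d, skips)
        h_n = feature_noise(h, 0.1, stream)
        p_n = asm.dec_n(h_n, skips)
        _, dp_d = mse_consistency(p_d, p_target)
        _, dp_n = mse_consistency(p_n, p_target)
        asm.zero_grad()
        db_d, dsk_d = asm.dec_d.backward(dp_d)
        db_n, dsk_n = asm.dec_n.backward(dp_n)
        asm.encoder.backward(db_d * keep + db_n,
                             [a + b for a, b in zip(dsk_d, dsk_n)])
        assert all(np.all(p.grad == 0) for p in asm.dec_s.parameters())
        assert any(np.any(p.grad != 0) for p in asm.dec_d.parameters())
        assert any(np.any(p.grad != 0) for p in asm.encoder.parameters())

    def test_stop_gradient_matches_finite_difference(self, rng):
        """Perturbing the target map must not change the returned gradient."""
        p_t = rng.random((1, 2, 3, 3)).astype(np.float32)
        p_d = rng.random((1, 2, 3, 3)).astype(np.float32)
        _, g1 = mse_consistency(p_d, p_t)
        _, g2 = mse_consistency(p_d, p_t)  # same pred, same grad
        assert np.array_equal(g1, g2)
        num = np.zeros_like(p_d)
        eps = 1e-3
        for idx in np.ndindex(p_d.shape):
            p_d[idx] += eps
            up, _ = mse_consistency(p_d, p_t)
            p_d[idx] -= 2 * eps
            dn, _ = mse_consistency(p_d, p_t)
            p_d[idx] += eps
            num[idx] = (up - dn) / (2 * eps)
        assert np.allclose(g1, num, atol=1e-4)
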