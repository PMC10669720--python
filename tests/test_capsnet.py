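"""Capsule network layers: squash, convolution, capsules, margin loss,
digitization, forward pass, and the analytic parameter audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcgcaps.autodiff import Tensor, conv2d
from pcgcaps.capsnet import (
    CapsNet,
    ConvSpec,
    MarginLossParams,
    NetworkConfig,
    PRESETS,
    count_params,
    digitize,
    margin_loss,
    squash,
)

rng = np.random.default_rng(3)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(squash(np.zeros(8)).data, 0.0)

    def test_unit_vector_norm_half(self):
        v = np.zeros(4)
        v[0] = 1.0
        out = squash(v).data
        assert np.isclose(np.linalg.norm(out), 0.5)

    def test_norm_three_maps_to_nine_tenths(self):
        v = np.array([3.0, 0.0])
        out = squash(v).data
        assert np.isclose(np.linalg.norm(out), 0.9)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_direction_preserved_norm_bounded(self, vals, scale):
        v = np.array(vals)
        if np.linalg.norm(v) < 1e-6:
            return
        out = squash(v).data
        n = np.linalg.norm(out)
        assert 0.0 <= n < 1.0
        cos = v @ out / (np.linalg.norm(v) * max(n, 1e-300))
        assert cos > 1 - 1e-9

    def test_norm_strictly_increasing_in_input_norm(self):
        u = np.array([1.0, 1.0])
        norms = [np.linalg.norm(squash(k * u).data) for k in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(norms, norms[1:]))


class TestConv:
    def test_reference_shape_chain(self):
        shapes = PRESETS["5s"].shapes()
        assert shapes["conv1"] == (60, 4, 256)
        assert shapes["primarycap_conv2d"] == (57, 1, 256)
        assert shapes["primarycap_reshape"] == (912, 16)
        assert shapes["digitcaps"] == (2, 16)
        assert shapes["decoder"] == (128, 16, 1)

    def test_one_by_one_identity_kernel(self):
        x = Tensor(rng.standard_normal((1, 5, 5, 1)))
        w = Tensor(np.ones((1, 1, 1, 1)))
        b = Tensor(np.zeros(1))
        out = conv2d(x, w, b, 1)
        assert np.allclose(out.data, x.data)

    def test_matches_quadruple_loop_oracle(self):
        # brute-force cross-correlation per the layer definition
        x = rng.standard_normal((1, 6, 6, 3))
        w = rng.standard_normal((3, 3, 3, 2))
        b = rng.standard_normal(2)
        out = conv2d(Tensor(x), Tensor(w), Tensor(b), 1).data[0]
        K, F = 3, 2
        expect = np.zeros((4, 4, F))
        for i in range(4):
            for j in range(4):
                for k in range(F):
                    acc = b[k]
                    for u in range(K):
                        for v in range(K):
                            for c in range(3):
                                acc += w[u, v, c, k] * x[0, i + u, j + v, c]
                    expect[i, j, k] = acc
        assert np.allclose(out, expect, atol=1e-10)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            conv2d(Tensor(np.zeros((1, 4, 4, 1))), Tensor(np.zeros((5, 5, 1, 1))),
                   None, 1)


class TestPrimaryCapsules:
    def test_count_and_dim(self):
        model = CapsNet(PRESETS["tiny"], seed=0)
        feats = Tensor(rng.standard_normal((2, 60, 4, 32)))
        caps = model.primary_capsules(feats)
        assert caps.shape == (2, 228, 8)

    def test_zero_features_give_zero_capsules(self):
        model = CapsNet(PRESETS["tiny"], seed=0)
        for b in (model.b_primary,):
            b.data[:] = 0.0
        caps = model.primary_capsules(Tensor(np.zeros((1, 60, 4, 32))))
        assert np.allclose(caps.data, 0.0)

    def test_all_norms_below_one(self):
        model = CapsNet(PRESETS["tiny"], seed=0)
        caps = model.primary_capsules(Tensor(rng.standard_normal((1, 60, 4, 32)) * 5))
        norms = np.linalg.norm(caps.data, axis=-1)
        assert np.all(norms < 1.0)

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_flattened_conv_output_divisible_by_capsule_dim(self, preset):
        # the capsule_dim x channels filter parametrization guarantees the
        # reshape is exact for every preset
        cfg = PRESETS[preset]
        h, w, _ = cfg.shapes()["primarycap_conv2d"]
        flat = h * w * cfg.primary_conv.filters
        assert flat % cfg.capsule_dim == 0
        assert cfg.n_primary * cfg.capsule_dim == flat


class TestDigitize:
    def test_direct_comparison(self):
        assert digitize(np.array([0.9, 0.2]), 0.5).tolist() == [1, 0]

    def test_strict_at_threshold(self):
        assert digitize(np.array([0.5]), 0.5).tolist() == [0]

    def test_small_threshold_limit(self):
        out = digitize(np.array([0.01, 0.9, 0.3]), 1e-6)
        assert out.tolist() == [1, 1, 1]

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            digitize(np.array([0.5]), 1.0)


class TestMarginLoss:
    def test_zero_when_margins_satisfied(self):
        loss = margin_loss(np.array([0.95, 0.05]), np.array([1.0, 0.0]))
        assert loss.data == 0.0

    def test_hand_computed_value(self):
        # (0.9-0.5)^2 + 0.5*(0.5-0.1)^2 = 0.16 + 0.08
        loss = margin_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert np.isclose(loss.data, 0.24)

    def test_monotone_in_norms(self):
        y = np.array([1.0, 0.0])
        true_up = [margin_loss(np.array([v, 0.5]), y).data for v in (0.2, 0.5, 0.8)]
        assert all(a >= b for a, b in zip(true_up, true_up[1:]))
        false_up = [margin_loss(np.array([0.5, v]), y).data for v in (0.2, 0.5, 0.8)]
        assert all(a <= b for a, b in zip(false_up, false_up[1:]))

    def test_nonnegative_and_batched(self):
        norms = rng.uniform(0, 1, size=(6, 2))
        y = np.eye(2)[rng.integers(0, 2, 6)]
        assert margin_loss(norms, y).data >= 0.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=0.1, m_minus=0.9)


class TestForward:
    def test_norms_in_unit_interval_and_recon_shape(self):
        model = CapsNet(PRESETS["tiny"], seed=1)
        x = rng.standard_normal((3, 128, 16, 1))
        out = model.forward(x)
        norms = out["norms"].data
        assert norms.shape == (3, 2)
        assert np.all((norms >= 0) & (norms < 1))
        assert out["reconstruction"].shape == (3, 128, 16, 1)
        assert out["prediction"].shape == (3, 2)

    def test_deterministic_across_calls(self):
        model = CapsNet(PRESETS["tiny"], seed=1)
        x = rng.standard_normal((2, 128, 16, 1))
        a = model.forward(x)["norms"].data
        b = model.forward(x)["norms"].data
        assert np.array_equal(a, b)

    def test_same_seed_same_model(self):
        x = rng.standard_normal((1, 128, 16, 1))
        a = CapsNet(PRESETS["tiny"], seed=5).forward(x)["norms"].data
        b = CapsNet(PRESETS["tiny"], seed=5).forward(x)["norms"].data
        assert np.array_equal(a, b)

    def test_shape_mismatch_names_preset(self):
        model = CapsNet(PRESETS["tiny"], seed=0)
        with pytest.raises(ValueError, match="tiny"):
            model.forward(np.zeros((1, 64, 16, 1)))

    def test_frame_shift_changes_norms_continuously(self):
        # translation probe: a one-frame circular shift moves the digit
        # norms by a bounded amount, not a jump to the extremes
        model = CapsNet(PRESETS["tiny"], seed=2)
        x = rng.standard_normal((128, 16))
        base = model.forward(x)["norms"].data[0]
        shifted = model.forward(np.roll(x, 1, axis=1))["norms"].data[0]
        assert np.all(np.abs(base - shifted) < 0.5)


class TestParamAudit:
    def test_reference_counts(self):
        counts = count_params(PRESETS["5s"])
        assert counts["conv1"] == 20_992
        assert counts["primarycap_conv2d"] == 1_048_832
        assert counts["digitcaps"] == 466_944
        assert counts["decoder"] == 6_329_344
        assert counts["total"] == 7_866_112

    @pytest.mark.parametrize("preset", ["tiny", "3s"])
    def test_analytic_count_matches_instantiated_model(self, preset):
        # independent oracle: sum of actual weight-array sizes
        model = CapsNet(PRESETS[preset], seed=0)
        assert model.n_params() == count_params(PRESETS[preset])["total"]


def test_checkpoint_roundtrip(tmp_path):
    model = CapsNet(PRESETS["tiny"], seed=9)
    model.input_offset, model.input_scale = -3.0, 7.5
    model.save(tmp_path / "ckpt")
    back = CapsNet.load(tmp_path / "ckpt")
    x = rng.standard_normal((2, 128, 16, 1))
    assert np.array_equal(model.forward(x)["norms"].data,
                          back.forward(x)["norms"].data)
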