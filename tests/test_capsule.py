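"""Capsule head: squash, votes, routing and margin loss against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (margin_loss_ref, self_attention_routing_ref, squash_ref,
                      votes_ref)
from molcarc.autodiff import Parameter, Tensor
from molcarc.capsule import (CapsuleLayer, CapsuleLayerParams, LossConfig,
                             capsule_lengths, compute_votes, dynamic_routing,
                             margin_loss, self_attention_routing, squash)

RNG = np.random.default_rng(99)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(squash(np.zeros((1, 4))).data, 0.0)

    def test_saturates_at_unit_length(self):
        v = squash(np.array([[1e6, 0.0]]))
        assert abs(np.linalg.norm(v.data) - 1.0) < 1e-6

    def test_unit_input_closed_form(self):
        v = squash(np.array([[1.0, 0.0]]))
        assert np.linalg.norm(v.data) == pytest.approx(1 - np.exp(-1), abs=1e-6)
        assert v.data[0, 1] == 0.0  # direction preserved

    def test_matches_reference_on_random_vectors(self):
        s = RNG.standard_normal((6, 3))
        v = squash(s).data
        for i in range(6):
            assert np.allclose(v[i], squash_ref(s[i]), atol=1e-9)

    @given(st.floats(min_value=1e-3, max_value=50), st.floats(min_value=1e-3, max_value=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_length_strictly_increasing_and_bounded(self, n1, n2):
        lo, hi = sorted([n1, n2])
        v_lo = np.linalg.norm(squash(np.array([[lo, 0.0]])).data)
        v_hi = np.linalg.norm(squash(np.array([[hi, 0.0]])).data)
        assert 0 < v_lo < 1 and 0 < v_hi < 1
        if hi > lo:
            assert v_hi > v_lo


class TestVotes:
    def test_identity_blocks_pass_inputs_through(self):
        u = RNG.standard_normal((2, 3, 2))
        W = np.zeros((3, 2, 2, 2))
        W[:, :] = np.eye(2)
        out = compute_votes(Tensor(u), Tensor(W)).data
        for j in range(2):
            assert np.allclose(out[:, :, j, :], u)

    def test_zero_input_gives_zero_votes(self):
        out = compute_votes(Tensor(np.zeros((1, 4, 3))),
                            Tensor(RNG.standard_normal((4, 2, 3, 2))))
        assert np.allclose(out.data, 0.0)

    def test_matches_explicit_loop_oracle(self):
        u = RNG.standard_normal((3, 2, 5))
        W = RNG.standard_normal((2, 4, 5, 3))
        out = compute_votes(Tensor(u), Tensor(W)).data
        assert np.abs(out - votes_ref(u, W)).max() < 1e-10

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_votes(Tensor(np.zeros((1, 2, 3))),
                          Tensor(np.zeros((2, 2, 4, 2))))


class TestSelfAttentionRouting:
    def test_singleton_output_capsule_couples_fully(self):
        u_hat = Tensor(RNG.standard_normal((2, 4, 1, 3)))
        v, state = self_attention_routing(u_hat, Tensor(np.zeros((4, 1))), 128.0)
        assert np.allclose(state["coupling"].data, 1.0)
        s_ref = u_hat.data.sum(axis=1)[:, 0, :]
        for b in range(2):
            assert np.allclose(v.data[b, 0], squash_ref(s_ref[b]), atol=1e-9)

    def test_identical_votes_split_coupling_evenly(self):
        one = RNG.standard_normal((3, 5, 1, 2))
        u_hat = Tensor(np.concatenate([one, one], axis=2))
        _, state = self_attention_routing(u_hat, Tensor(np.zeros((5, 2))), 128.0)
        assert np.allclose(state["coupling"].data, 0.5, atol=1e-12)

    def test_matches_explicit_scalar_loop_oracle(self):
        u_hat = RNG.standard_normal((2, 3, 2, 2))
        B = RNG.standard_normal((3, 2))
        v, state = self_attention_routing(Tensor(u_hat), Tensor(B), 7.0)
        v_ref, C_ref = self_attention_routing_ref(u_hat, B, 7.0)
        assert np.abs(v.data - v_ref).max() < 1e-6
        assert np.abs(state["coupling"].data - C_ref).max() < 1e-6

    @given(st.integers(2, 6), st.integers(2, 4), st.integers(1, 3))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_coupling_sums_to_one_over_output_capsules(self, n_in, n_out, b):
        rng = np.random.default_rng(n_in * 100 + n_out * 10 + b)
        u_hat = Tensor(rng.standard_normal((b, n_in, n_out, 2)))
        _, state = self_attention_routing(u_hat, Tensor(np.zeros((n_in, n_out))), 128.0)
        assert np.abs(state["coupling"].data.sum(axis=2) - 1.0).max() < 1e-6

    def test_equivariant_to_joint_rotation_of_one_output_capsule(self):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        u_hat = RNG.standard_normal((1, 4, 2, 2))
        B = RNG.standard_normal((4, 2))
        v0, _ = self_attention_routing(Tensor(u_hat), Tensor(B), 16.0)
        rotated = u_hat.copy()
        rotated[:, :, 1, :] = rotated[:, :, 1, :] @ R.T
        v1, _ = self_attention_routing(Tensor(rotated), Tensor(B), 16.0)
        assert np.allclose(v1.data[0, 0], v0.data[0, 0], atol=1e-10)
        assert np.allclose(v1.data[0, 1], v0.data[0, 1] @ R.T, atol=1e-10)

    def test_output_lengths_in_unit_interval(self):
        u_hat = Tensor(RNG.standard_normal((4, 16, 2, 2)))
        v, _ = self_attention_routing(u_hat, Tensor(np.zeros((16, 2))), 128.0)
        lengths = capsule_lengths(v).data
        assert np.all(lengths >= 0) and np.all(lengths < 1)
        # extreme votes saturate to exactly 1.0 only at float precision
        huge, _ = self_attention_routing(
            Tensor(1e6 * np.ones((1, 16, 2, 2))), Tensor(np.zeros((16, 2))), 128.0)
        assert np.all(capsule_lengths(huge).data <= 1.0 + 1e-9)


class TestDynamicRouting:
    def test_three_iteration_routing_shapes_and_coupling(self):
        u_hat = Tensor(RNG.standard_normal((2, 5, 2, 3)))
        v, state = dynamic_routing(u_hat, n_iters=3)
        assert v.shape == (2, 2, 3)
        assert np.abs(state["coupling"].data.sum(axis=2) - 1.0).max() < 1e-6

    def test_agreement_concentrates_coupling(self):
        # four aligned votes for capsule 0, noise votes for capsule 1
        u_hat = np.zeros((1, 4, 2, 2))
        u_hat[0, :, 0, :] = [3.0, 0.0]
        u_hat[0, :, 1, :] = RNG.standard_normal((4, 2)) * 0.1
        _, state = dynamic_routing(Tensor(u_hat), n_iters=3)
        assert np.all(state["coupling"].data[0, :, 0] > 0.5)


class TestMarginLoss:
    CONFIG = LossConfig()

    def test_satisfied_margins_give_zero_loss(self):
        loss = margin_loss(Tensor(np.array([[0.05, 0.95]])), np.array([[0, 1]]))
        assert loss.data == 0.0

    def test_missed_true_class_costs_081(self):
        loss = margin_loss(Tensor(np.array([[0.0, 0.05]])), np.array([[1, 0]]))
        assert loss.data == pytest.approx(0.81, abs=1e-12)  # (0.9 - 0)^2

    def test_confident_wrong_class_costs_0405(self):
        loss = margin_loss(Tensor(np.array([[0.95, 1.0]])), np.array([[1, 0]]))
        assert loss.data == pytest.approx(0.405, abs=1e-12)  # 0.5 * (1 - 0.1)^2

    def test_matches_reference_and_batch_averages(self):
        norms = RNG.random((8, 2))
        onehot = np.eye(2)[RNG.integers(0, 2, 8)]
        loss = margin_loss(Tensor(norms), onehot).data
        assert loss == pytest.approx(margin_loss_ref(norms, onehot), abs=1e-12)

    def test_out_of_range_lengths_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(Tensor(np.array([[1.2, 0.1]])), np.array([[1, 0]]))

    def test_gradient_matches_finite_differences(self):
        p = Parameter(RNG.random((4, 2)) * 0.8 + 0.05)
        onehot = np.eye(2)[[0, 1, 1, 0]]

        def fn():
            return margin_loss(p * 1.0, onehot)
        loss = fn()
        loss.backward()
        g = p.grad.copy()
        eps = 1e-6
        for ix in [(0, 0), (1, 1), (3, 0)]:
            p.data[ix] += eps
            lp = fn().data
            p.data[ix] -= 2 * eps
            lm = fn().data
            p.data[ix] += eps
            assert abs((lp - lm) / (2 * eps) - g[ix]) < 1e-4


class TestCapsuleLayer:
    def test_full_head_end_to_end_shapes(self):
        layer = CapsuleLayer(CapsuleLayerParams(), np.random.default_rng(0))
        u = squash(Tensor(RNG.standard_normal((3, 16, 8))))
        v, state = layer(u)
        assert v.shape == (3, 2, 2)
        assert np.abs(state["coupling"].data.sum(axis=2) - 1.0).max() < 1e-6

    def test_sqrt_stabilizer_flag_changes_coupling(self):
        u = squash(Tensor(RNG.standard_normal((2, 16, 8))))
        a = CapsuleLayer(CapsuleLayerParams(), np.random.default_rng(1))
        b = CapsuleLayer(CapsuleLayerParams(sqrt_stabilizer=True),
                         np.random.default_rng(1))
        _, sa = a(u)
        _, sb = b(u)
        assert not np.allclose(sa["coupling"].data, sb["coupling"].data)
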