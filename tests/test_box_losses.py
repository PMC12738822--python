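"""Unit and property tests of the IoU / WIoU / Inner-WIoU loss chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yolodcpg.autograd import Tensor
from yolodcpg.box_losses import (DENSE_SMALL_TARGET_RATIO, WIoUConfig,
                                 WIoUState, box_loss, inner_iou,
                                 inner_wiou_loss, iou, make_inner_box,
                                 wiou_distance_penalty, wiou_v1, wiou_v3)
from conftest import rasterized_iou

boxes_st = st.tuples(
    st.floats(-5, 5), st.floats(-5, 5),
    st.floats(0.1, 6), st.floats(0.1, 6),
).map(lambda t: tuple(round(v, 3) for v in t))


class TestIoU:
    @pytest.mark.parametrize("pred,gt,expected", [
        ((5, 5, 2, 2), (5, 5, 2, 2), 1.0),
        ((0, 0, 2, 2), (100, 100, 2, 2), 0.0),
        ((0.5, 0.5, 1, 1), (1.0, 0.5, 1, 1), 1 / 3),
        ((0, 0, 2, 2), (2, 0, 2, 2), 0.0),     # touching edges
    ])
    def test_reference_values(self, pred, gt, expected):
        assert iou(pred, gt) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_boxes_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert iou((0, 0, 0, 0), (0, 0, 0, 0)) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(boxes_st, boxes_st)
    def test_range_symmetry_and_oracle(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a), abs=1e-12)
        assert v == pytest.approx(rasterized_iou(a, b), abs=1e-3)

    def test_vectorized_matches_scalar(self, rng):
        a = np.column_stack([rng.uniform(-5, 5, 50), rng.uniform(-5, 5, 50),
                             rng.uniform(0.1, 4, 50), rng.uniform(0.1, 4, 50)])
        b = a[::-1].copy()
        vec = iou(a, b)
        for i in range(50):
            assert vec[i] == pytest.approx(iou(tuple(a[i]), tuple(b[i])), abs=1e-12)


class TestInnerBox:
    @pytest.mark.parametrize("b,ratio,expected", [
        ((10, 10, 4, 2), 0.5, (9, 11, 9.5, 10.5)),
        ((10, 10, 4, 2), 1.0, (8, 12, 9, 11)),
        ((0, 0, 2, 2), 1.5, (-1.5, 1.5, -1.5, 1.5)),
    ])
    def test_corners(self, b, ratio, expected):
        np.testing.assert_allclose(make_inner_box(b, ratio), expected, atol=1e-12)

    @pytest.mark.parametrize("ratio", [0.49, 1.51, -1.0])
    def test_ratio_out_of_range_rejected(self, ratio):
        with pytest.raises(ValueError):
            make_inner_box((0, 0, 1, 1), ratio)


class TestInnerIoU:
    def test_identical_boxes_any_ratio(self, rng):
        for ratio in (0.5, 0.7, 1.0, 1.05, 1.5):
            b = tuple(rng.uniform(0.5, 3, 4))
            assert inner_iou(b, b, ratio) == pytest.approx(1.0)

    def test_ratio_one_equals_iou_on_1000_pairs(self, rng):
        a = np.column_stack([rng.uniform(-5, 5, 1000), rng.uniform(-5, 5, 1000),
                             rng.uniform(0.05, 4, 1000), rng.uniform(0.05, 4, 1000)])
        b = np.column_stack([rng.uniform(-5, 5, 1000), rng.uniform(-5, 5, 1000),
                             rng.uniform(0.05, 4, 1000), rng.uniform(0.05, 4, 1000)])
        np.testing.assert_array_equal(inner_iou(a, b, 1.0), iou(a, b))

    def test_shrunk_boxes_just_touch(self):
        assert inner_iou((0.5, 0.5, 1, 1), (1.0, 0.5, 1, 1), 0.5) == 0.0

    def test_disjoint_inner_boxes_clamped_not_negative(self):
        # the printed inter formula would go negative here
        assert inner_iou((0, 0, 1, 1), (10, 10, 1, 1), 0.5) == 0.0

    def test_monotone_in_ratio_for_concentric_boxes(self, rng):
        for _ in range(20):
            c = rng.uniform(-2, 2, 2)
            a = (c[0], c[1], rng.uniform(0.5, 2), rng.uniform(0.5, 2))
            b = (c[0], c[1], rng.uniform(0.5, 2), rng.uniform(0.5, 2))
            vals = [inner_iou(a, b, r) for r in np.linspace(0.5, 1.5, 11)]
            assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_matches_rasterization_oracle(self, rng):
        for _ in range(30):
            a = tuple(np.r_[rng.uniform(-3, 3, 2), rng.uniform(0.2, 3, 2)])
            b = tuple(np.r_[rng.uniform(-3, 3, 2), rng.uniform(0.2, 3, 2)])
            ratio = rng.uniform(0.5, 1.5)
            scaled_a = (a[0], a[1], a[2] * ratio, a[3] * ratio)
            scaled_b = (b[0], b[1], b[2] * ratio, b[3] * ratio)
            assert inner_iou(a, b, ratio) == pytest.approx(
                rasterized_iou(scaled_a, scaled_b), abs=1e-3)


class TestDistancePenalty:
    def test_coincident_centers_give_one(self):
        assert wiou_distance_penalty((1, 1, 2, 5), (1, 1, 4, 1)) == pytest.approx(1.0)

    def test_reference_values_both_modes(self):
        p, g = (0, 0, 2, 2), (2, 0, 2, 2)
        assert wiou_distance_penalty(p, g, "sum_squared") == pytest.approx(np.exp(0.2))
        assert wiou_distance_penalty(p, g, "squared_sum") == pytest.approx(np.exp(4 / 36))

    def test_point_boxes_return_one(self):
        assert wiou_distance_penalty((1, 1, 0, 0), (1, 1, 0, 0)) == 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(boxes_st, boxes_st)
    def test_at_least_one_and_one_iff_coincident(self, a, b):
        v = wiou_distance_penalty(a, b)
        assert v >= 1.0
        coincident = (a[0], a[1]) == (b[0], b[1])
        assert (v == pytest.approx(1.0)) == coincident


class TestWIoUv1:
    def test_zero_for_identical(self):
        assert wiou_v1((3, 4, 2, 1), (3, 4, 2, 1)) == pytest.approx(0.0)

    def test_coincident_centers_reduce_to_iou_loss(self):
        p, g = (1, 1, 2, 2), (1, 1, 4, 4)  # iou = 0.25
        assert wiou_v1(p, g) == pytest.approx(0.75)

    def test_touching_boxes(self):
        assert wiou_v1((0, 0, 2, 2), (2, 0, 2, 2)) == pytest.approx(np.exp(0.2))


class TestWIoUv3:
    def test_beta_at_pivot_gives_unit_gain(self):
        cfg = WIoUConfig(alpha=1.9, delta=3.0)
        p, g = (0, 0, 2, 2), (1, 0, 2, 2)
        liou = 1 - iou(p, g)
        state = WIoUState(running_mean_liou=liou / cfg.delta, initialized=True)
        loss, _ = wiou_v3(p, g, cfg, state)
        assert loss == pytest.approx(wiou_v1(p, g), rel=1e-6)

    def test_identical_boxes_zero_loss_any_state(self):
        for mean in (0.1, 1.0, 5.0):
            state = WIoUState(mean, True)
            loss, _ = wiou_v3((2, 2, 1, 1), (2, 2, 1, 1), WIoUConfig(), state)
            assert loss == pytest.approx(0.0)

    def test_hand_computed_gain(self):
        # beta = 1: r = 1 / (3 * 1.9^-2) = 1.9^2 / 3
        cfg = WIoUConfig(alpha=1.9, delta=3.0)
        p, g = (0, 0, 2, 2), (1, 0, 2, 2)
        liou = 1 - iou(p, g)
        state = WIoUState(running_mean_liou=liou, initialized=True)
        loss, _ = wiou_v3(p, g, cfg, state)
        assert loss == pytest.approx(1.9 ** 2 / 3 * wiou_v1(p, g), rel=1e-6)

    def test_uninitialized_state_seeds_from_first_batch(self, rng):
        p = np.column_stack([rng.uniform(0, 4, 8), rng.uniform(0, 4, 8),
                             rng.uniform(0.5, 2, 8), rng.uniform(0.5, 2, 8)])
        g = p + rng.normal(0, 0.2, p.shape)
        g[:, 2:] = np.abs(g[:, 2:]) + 0.1
        state = WIoUState()
        _, state = wiou_v3(p, g, WIoUConfig(), state)
        assert state.initialized
        assert state.running_mean_liou == pytest.approx(np.mean(1 - iou(p, g)))

    def test_state_update_is_momentum_ema(self):
        cfg = WIoUConfig(momentum=0.1)
        state = WIoUState(0.5, True)
        p, g = (0, 0, 2, 2), (1, 0, 2, 2)
        liou = 1 - iou(p, g)
        wiou_v3(p, g, cfg, state)
        assert state.running_mean_liou == pytest.approx(0.5 + 0.1 * (liou - 0.5))


class TestInnerWIoU:
    def test_zero_for_identical_all_ratios_and_states(self, rng):
        for ratio in (0.5, 0.7, 1.0, DENSE_SMALL_TARGET_RATIO, 1.5):
            for mean in (0.05, 1.0):
                b = tuple(rng.uniform(0.5, 3, 4))
                loss, _ = inner_wiou_loss(b, b, WIoUConfig(ratio=ratio),
                                          WIoUState(mean, True))
                assert loss == pytest.approx(0.0, abs=1e-9)

    def test_ratio_one_reduces_to_wiou_v3(self, rng):
        p = np.column_stack([rng.uniform(0, 4, 16), rng.uniform(0, 4, 16),
                             rng.uniform(0.5, 2, 16), rng.uniform(0.5, 2, 16)])
        g = np.column_stack([rng.uniform(0, 4, 16), rng.uniform(0, 4, 16),
                             rng.uniform(0.5, 2, 16), rng.uniform(0.5, 2, 16)])
        cfg = WIoUConfig(ratio=1.0)
        l1, _ = inner_wiou_loss(p, g, cfg, WIoUState(0.4, True))
        l2, _ = wiou_v3(p, g, cfg, WIoUState(0.4, True))
        assert l1 == pytest.approx(l2, rel=1e-7)

    def test_composition_against_component_oracle(self):
        # pred/gt of the worked example; beta = delta so the v3 gain is 1
        p, g = (0.5, 0.5, 1, 1), (1.0, 0.5, 1, 1)
        cfg = WIoUConfig(ratio=0.5)
        liou = 1 - iou(p, g)
        state = WIoUState(liou / cfg.delta, True)
        loss, _ = inner_wiou_loss(p, g, cfg, state)
        expected = wiou_v1(p, g) + iou(p, g) - inner_iou(p, g, 0.5)
        assert inner_iou(p, g, 0.5) == 0.0
        assert iou(p, g) == pytest.approx(1 / 3)
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_loss_selector_dispatch(self):
        p, g = (0, 0, 2, 2), (1, 0, 2, 2)
        val, _ = box_loss("iou", p, g)
        assert val == pytest.approx(1 - iou(p, g))
        with pytest.raises(ValueError):
            box_loss("giou", p, g)


class TestGradients:
    @staticmethod
    def _frozen_oracle(p0, g, cfg, mean):
        """Inner-WIoU with the detached factors (v3 gain, enclosing-box
        normaliser) frozen at the base point — the reference for the custom
        gradient semantics."""
        liou0 = 1 - iou(tuple(p0), tuple(g))
        beta = liou0 / mean
        r0 = beta / (cfg.delta * cfg.alpha ** (beta - cfg.delta))
        wg = max(p0[0] + p0[2] / 2, g[0] + g[2] / 2) - min(p0[0] - p0[2] / 2, g[0] - g[2] / 2)
        hg = max(p0[1] + p0[3] / 2, g[1] + g[3] / 2) - min(p0[1] - p0[3] / 2, g[1] - g[3] / 2)
        d0 = wg ** 2 + hg ** 2

        def f(p):
            pen = np.exp(((p[0] - g[0]) ** 2 + (p[1] - g[1]) ** 2) / d0)
            return (r0 * pen * (1 - iou(tuple(p), tuple(g)))
                    + iou(tuple(p), tuple(g)) - inner_iou(tuple(p), tuple(g), cfg.ratio))
        return f

    @pytest.mark.parametrize("ratio", [0.7, 1.0, 1.05])
    def test_autodiff_matches_finite_differences(self, ratio, rng):
        cfg = WIoUConfig(ratio=ratio)
        for _ in range(5):
            p0 = np.array([rng.uniform(0, 2), rng.uniform(0, 2),
                           rng.uniform(0.8, 2), rng.uniform(0.8, 2)])
            g = p0 + np.array([0.3, -0.2, 0.1, 0.15])
            p = Tensor(p0.copy())
            p.requires_grad = True
            loss, _ = inner_wiou_loss(p, g, cfg, WIoUState(0.5, True))
            loss.backward()
            f = self._frozen_oracle(p0, g, cfg, 0.5)
            for i in range(4):
                e = np.zeros(4)
                e[i] = 1e-6
                fd = (f(p0 + e) - f(p0 - e)) / 2e-6
                assert p.grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_inner_term_sharpens_gradient_for_high_iou_pairs(self):
        """With ratio < 1 and high IoU, the auxiliary-box term contributes a
        larger |d/dcx| than the plain IoU loss."""
        g = np.array([1.0, 1.0, 2.0, 2.0])
        for dx in (0.02, 0.05, 0.1):
            p0 = g + np.array([dx, 0, 0, 0])

            def grad_cx(fn):
                p = Tensor(p0.copy())
                p.requires_grad = True
                fn(p).backward()
                return abs(p.grad[0])

            g_inner = grad_cx(lambda p: 1.0 - __import__("yolodcpg").inner_iou(p, g, 0.5))
            g_plain = grad_cx(lambda p: 1.0 - __import__("yolodcpg").iou(p, g))
            assert g_inner > g_plain
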