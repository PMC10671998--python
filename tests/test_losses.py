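import numpy as np
import pytest
from skimage.metrics import structural_similarity

from octdet.data_io import BoundingBox, BoxArray
from octdet.losses import (iou, lloss, lloss_tensor, loss_difference,
                           loss_iou, loss_mse, render_box_mask, ssim)
from octdet.nn import Tensor


def raster_iou(a: BoundingBox, b: BoundingBox, n: int = 1000) -> float:
    """Independent oracle: rasterize both boxes on an n x n grid and count."""
    def mask(box):
        m = np.zeros((n, n), dtype=bool)
        m[int(round(box.y_min * n)):int(round(box.y_max * n)),
          int(round(box.x_min * n)):int(round(box.x_max * n))] = True
        return m
    ma, mb = mask(a), mask(b)
    union = (ma | mb).sum()
    return (ma & mb).sum() / union if union else 0.0


def single_box_array(box: BoundingBox, k: int = 3) -> BoxArray:
    return BoxArray.from_boxes([box], k)


class TestIou:
    def test_identical_boxes(self):
        b = BoundingBox(0, 0, 0.5, 0.5)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 0.2, 0.2),
                   BoundingBox(0.5, 0.5, 0.7, 0.7)) == 0.0

    def test_worked_overlap_is_one_seventh(self):
        a = BoundingBox(0, 0, 0.2, 0.2)
        b = BoundingBox(0.1, 0.1, 0.3, 0.3)
        assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)
        assert raster_iou(a, b) == pytest.approx(1 / 7, abs=2e-3)

    def test_two_sentinels_define_zero(self):
        s = BoundingBox.sentinel()
        assert iou(s, s) == 0.0

    def test_symmetry_bounds_and_raster_agreement(self, rng):
        # boxes drawn on the oracle's own 1/1000 lattice, where cell counting
        # is exact and the comparison isolates the geometric computation
        from conftest import random_box

        def lattice_box():
            b = random_box(rng, 0.05)
            q = np.round(np.array(b.as_tuple()) * 1000) / 1000
            return BoundingBox(*q)

        for _ in range(1000):
            a, b = lattice_box(), lattice_box()
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a), abs=1e-15)
            assert v == pytest.approx(raster_iou(a, b), abs=2e-3)


class TestLossIou:
    def test_perfect_prediction(self):
        arr = single_box_array(BoundingBox(0.2, 0.2, 0.4, 0.4))
        assert loss_iou(arr, arr) == pytest.approx(0.0, abs=1e-9)

    def test_fully_disjoint_single_pair(self):
        p = single_box_array(BoundingBox(0, 0, 0.2, 0.2), k=1)
        a = single_box_array(BoundingBox(0.5, 0.5, 0.7, 0.7), k=1)
        assert loss_iou(p, a) == pytest.approx(1.0, abs=1e-9)

    def test_worked_pair_six_sevenths(self):
        p = single_box_array(BoundingBox(0, 0, 0.2, 0.2), k=1)
        a = single_box_array(BoundingBox(0.1, 0.1, 0.3, 0.3), k=1)
        assert loss_iou(p, a) == pytest.approx(6 / 7, abs=1e-6)

    def test_all_sentinel_returns_zero(self):
        empty = BoxArray(np.zeros((3, 4)))
        assert loss_iou(empty, empty) == 0.0


class TestLossMse:
    def test_zero_on_equality(self):
        arr = single_box_array(BoundingBox(0.2, 0.2, 0.4, 0.4))
        assert loss_mse(arr, arr) == 0.0

    def test_hand_computed_value(self):
        pred = BoxArray(np.zeros((1, 4)))
        actual = single_box_array(BoundingBox(0.2, 0.2, 0.4, 0.4), k=1)
        assert loss_mse(pred, actual) == pytest.approx(0.10, abs=1e-12)

    def test_symmetric(self, rng):
        from conftest import random_box
        p = single_box_array(random_box(rng))
        a = single_box_array(random_box(rng))
        assert loss_mse(p, a) == loss_mse(a, p)


class TestLossDifference:
    def test_zero_for_identical_arrays(self):
        arr = single_box_array(BoundingBox(0.2, 0.2, 0.5, 0.5))
        assert loss_difference(arr, arr, (64, 64)) == pytest.approx(0.0, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        from conftest import random_box
        for _ in range(20):
            p = single_box_array(random_box(rng))
            a = single_box_array(random_box(rng))
            v = loss_difference(p, a, (64, 64))
            assert 0.0 <= v <= 1.0

    def test_agrees_with_reference_ssim(self):
        # centered box vs the same box shifted by half the image; the SSIM
        # implementation must agree with the reference windowed SSIM to 1e-6
        p = single_box_array(BoundingBox(0.3, 0.3, 0.5, 0.5), k=1)
        a = single_box_array(BoundingBox(0.8, 0.8, 1.0, 1.0), k=1)
        shape = (96, 96)
        mask_p = render_box_mask(p.boxes, shape).data
        mask_a = render_box_mask(a.boxes, shape).data
        ref = structural_similarity(mask_p, mask_a, win_size=7, data_range=1.0,
                                    gaussian_weights=False)
        mine = ssim(mask_p, mask_a).item()
        assert mine == pytest.approx(ref, abs=1e-6)
        assert loss_difference(p, a, shape) == pytest.approx(
            1.0 - np.clip(ref, 0.0, 1.0), abs=1e-6)

    def test_both_empty_is_zero(self):
        empty = BoxArray(np.zeros((3, 4)))
        assert loss_difference(empty, empty, (64, 64)) == pytest.approx(0.0,
                                                                        abs=1e-9)


class TestCombinedLoss:
    def test_zero_iff_equal(self, rng):
        from conftest import random_box
        arr = single_box_array(random_box(rng))
        breakdown = lloss(arr, arr, (64, 64))
        assert breakdown.l_total == pytest.approx(0.0, abs=1e-8)
        other = single_box_array(random_box(rng))
        if not np.allclose(arr.boxes, other.boxes):
            assert lloss(arr, other, (64, 64)).l_total > 1e-4

    def test_total_is_mean_of_components(self, rng):
        from conftest import random_box
        p = single_box_array(random_box(rng))
        a = single_box_array(random_box(rng))
        b = lloss(p, a, (64, 64))
        assert b.l_total == pytest.approx(
            (b.l_mse + b.l_difference + b.l_iou) / 3, abs=1e-12)
        assert 0.0 <= b.l_total <= 1.0

    def test_composes_component_oracles(self):
        pred = BoxArray(np.zeros((1, 4)))
        actual = single_box_array(BoundingBox(0.2, 0.2, 0.4, 0.4), k=1)
        b = lloss(pred, actual, (64, 64))
        assert b.l_mse == pytest.approx(0.10, abs=1e-12)
        assert b.l_iou == pytest.approx(1.0, abs=1e-9)
        expected_diff = loss_difference(pred, actual, (64, 64))
        assert b.l_total == pytest.approx(
            (0.10 + expected_diff + 1.0) / 3, abs=1e-8)

    def test_monotone_decrease_along_translation(self):
        # slide a disjoint predicted box toward the target in 20 steps
        actual = single_box_array(BoundingBox(0.6, 0.6, 0.8, 0.8), k=1)
        totals = []
        for t in np.linspace(0.0, 1.0, 20):
            x0 = 0.05 + t * (0.6 - 0.05)
            y0 = 0.05 + t * (0.6 - 0.05)
            pred = single_box_array(BoundingBox(x0, y0, x0 + 0.2, y0 + 0.2),
                                    k=1)
            totals.append(lloss(pred, actual, (64, 64)).l_total)
        assert all(b < a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_gradient_matches_finite_differences(self):
        # coordinates chosen off pixel boundaries of the 48-px raster grid,
        # where the anti-aliased mask edges are smooth
        p0 = np.array([[0.2531, 0.2447, 0.5563, 0.6082]])
        a0 = np.array([[0.3011, 0.3531, 0.6043, 0.6529]])
        t = Tensor(p0.copy(), requires_grad=True)
        total, _ = lloss_tensor(t, a0, (48, 48))
        total.backward()

        def f(arr):
            tt, _ = lloss_tensor(Tensor(arr), a0, (48, 48))
            return tt.item()

        eps = 1e-6
        num = np.zeros_like(p0)
        for i in range(4):
            hi, lo = p0.copy(), p0.copy()
            hi[0, i] += eps
            lo[0, i] -= eps
            num[0, i] = (f(hi) - f(lo)) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-5, rtol=1e-3)
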