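"""Box geometry and the IoU-loss family.

Frozen expected values were computed with an independent straight-line
transcription of the cost formulas evaluated in exact arithmetic (sympy)
before this module existed; the rasterization oracle counts unit cells on a
fine grid.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kyolo import boxes as B
from kyolo.autodiff import Tensor
from kyolo.boxes import BoundingBox, LossConfig

from conftest import random_boxes


def box_strategy():
    coord = st.floats(0.2, 0.8)
    size = st.floats(0.05, 0.5)
    return st.builds(BoundingBox, coord, coord, size, size)


class TestIoU:
    def test_identity_and_disjoint(self):
        a = BoundingBox(0.5, 0.5, 0.2, 0.2)
        assert B.iou(a, a) == pytest.approx(1.0, abs=1e-6)
        b = BoundingBox(0.1, 0.1, 0.05, 0.05)
        assert B.iou(a, b) == 0.0

    def test_known_overlap(self):
        # corners (0,0,2,2) vs (1,1,3,3): intersection 1, union 7
        a = BoundingBox.from_corners(0, 0, 2, 2)
        b = BoundingBox.from_corners(1, 1, 3, 3)
        assert B.iou(a, b) == pytest.approx(1 / 7, abs=1e-6)

    def test_invalid_box_rejected(self):
        with pytest.raises(B.InvalidBoxError):
            BoundingBox(0.5, 0.5, 0.0, 0.2)
        with pytest.raises(B.InvalidBoxError):
            B.iou(np.array([0.5, 0.5, -0.1, 0.2]), np.array([0.5, 0.5, 0.1, 0.2]))

    def test_symmetric_bounded_equality_iff_identical(self, rng):
        a = random_boxes(rng, 10_000)
        b = random_boxes(rng, 10_000)
        iou_ab = np.asarray(B.iou(a, b))
        iou_ba = np.asarray(B.iou(b, a))
        np.testing.assert_allclose(iou_ab, iou_ba, rtol=1e-12)
        assert np.all((iou_ab >= 0) & (iou_ab <= 1))
        assert np.all(iou_ab[np.all(np.isclose(a, b), axis=1)] > 0.999)
        # strictly below 1 whenever the boxes differ materially
        differ = np.abs(a - b).max(axis=1) > 1e-3
        assert np.all(iou_ab[differ] < 1.0)

    def test_matches_rasterization_oracle(self, rng):
        """Counting cells of a 1/1000 grid agrees with the closed form."""
        res = 1000
        for _ in range(20):
            a, b = random_boxes(rng, 2)
            grids = []
            for bx in (a, b):
                x1, y1 = ((bx[:2] - bx[2:] / 2) * res).astype(int)
                x2, y2 = ((bx[:2] + bx[2:] / 2) * res).astype(int)
                g = np.zeros((res, res), dtype=bool)
                g[y1:y2, x1:x2] = True
                grids.append(g)
            inter = np.logical_and(*grids).sum()
            union = np.logical_or(*grids).sum()
            assert B.iou(a, b) == pytest.approx(inter / union, abs=1e-2)


class TestEnclosure:
    def test_coincident_centers(self):
        g = B.enclosure(BoundingBox(0.5, 0.5, 0.2, 0.1), BoundingBox(0.5, 0.5, 0.1, 0.3))
        assert g.s_cw == g.s_ch == g.d == 0.0

    def test_three_four_five_triangle(self):
        g = B.enclosure(BoundingBox(0, 0, 1, 1), BoundingBox(3, 4, 1, 1))
        assert (g.s_cw, g.s_ch, g.d) == (3.0, 4.0, 5.0)

    def test_containment_uses_outer_box(self):
        inner = BoundingBox(0.5, 0.5, 0.1, 0.1)
        outer = BoundingBox(0.5, 0.5, 0.4, 0.6)
        g = B.enclosure(inner, outer)
        assert g.cw == pytest.approx(0.4) and g.ch == pytest.approx(0.6)

    def test_invariants_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = random_boxes(rng, 2)
            g = B.enclosure(a, b)
            assert g.d**2 == pytest.approx(g.s_cw**2 + g.s_ch**2, rel=1e-9)
            assert 0 <= g.s_ch <= g.d + 1e-12
            assert g.cw >= max(a[2], b[2]) - 1e-12
            assert g.ch >= max(a[3], b[3]) - 1e-12


class TestAngleCost:
    def test_cardinal_and_diagonal_offsets(self):
        mk = lambda dx, dy: B.enclosure(BoundingBox(0.3, 0.3, 0.1, 0.1),
                                        BoundingBox(0.3 + dx, 0.3 + dy, 0.1, 0.1))
        assert B.angle_cost(mk(0.2, 0.0)) == pytest.approx(0.0, abs=1e-12)
        assert B.angle_cost(mk(0.0, 0.2)) == pytest.approx(0.0, abs=1e-12)
        assert B.angle_cost(mk(0.2, 0.2)) == pytest.approx(1.0, abs=1e-12)
        assert B.angle_cost(mk(0.0, 0.0)) == 0.0  # coincident centers

    def test_matches_trigonometric_transcription(self, rng):
        """The closed form 2*s_cw*s_ch/d^2 equals the arcsin/sin form."""
        for _ in range(500):
            a, b = random_boxes(rng, 2)
            g = B.enclosure(a, b)
            if g.d < 1e-9:
                continue
            direct = 1.0 - 2.0 * math.sin(math.asin(min(g.s_ch / g.d, 1.0)) - math.pi / 4) ** 2
            assert B.angle_cost(g) == pytest.approx(direct, abs=1e-9)

    def test_complementary_angle_symmetry(self, rng):
        for _ in range(200):
            dx, dy = np.random.default_rng(int(rng.integers(1 << 30))).uniform(0.01, 0.3, 2)
            g1 = B.enclosure(BoundingBox(0.3, 0.3, 0.1, 0.1),
                             BoundingBox(0.3 + dx, 0.3 + dy, 0.1, 0.1))
            g2 = B.enclosure(BoundingBox(0.3, 0.3, 0.1, 0.1),
                             BoundingBox(0.3 + dy, 0.3 + dx, 0.1, 0.1))
            assert B.angle_cost(g1) == pytest.approx(B.angle_cost(g2), abs=1e-12)


class TestDistanceShapeCosts:
    def test_distance_zero_at_coincident_centers(self):
        g = B.enclosure(BoundingBox(0.5, 0.5, 0.2, 0.2), BoundingBox(0.5, 0.5, 0.1, 0.1))
        assert B.distance_cost(g, 0.0) == 0.0

    def test_distance_frozen_value(self):
        # px = py = 1, gamma = 2: 2 - 2e^-2 = 1.7293294335267746 (exact arith.)
        g = B.EnclosureGeometry(cw=1.0, ch=1.0, s_cw=1.0, s_ch=1.0, d=math.sqrt(2))
        assert B.distance_cost(g, 0.0) == pytest.approx(1.7293294335267746, abs=1e-12)

    def test_distance_monotone_in_offset(self):
        vals = [B.distance_cost(B.EnclosureGeometry(1, 1, s, 0.0, s), 0.0)
                for s in np.linspace(0.01, 0.99, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_shape_identical_and_frozen(self):
        a = BoundingBox(0.5, 0.5, 0.2, 0.3)
        assert B.shape_cost(a, a) == 0.0
        # W = 2*Wgt, H = Hgt, theta=4: (1 - e^{-1/2})^4 = 0.02396865082101361
        v = B.shape_cost(BoundingBox(0, 0, 2, 1), BoundingBox(0, 0, 1, 1), theta=4)
        assert v == pytest.approx(0.023968650821013612, abs=1e-12)

    def test_shape_symmetric_and_monotone(self, rng):
        a = BoundingBox(0.5, 0.5, 0.2, 0.3)
        b = BoundingBox(0.4, 0.6, 0.35, 0.1)
        assert B.shape_cost(a, b) == pytest.approx(B.shape_cost(b, a), abs=1e-15)
        vals = [B.shape_cost(BoundingBox(0, 0, w, 1), BoundingBox(0, 0, 1, 1))
                for w in np.linspace(1.0, 4.0, 15)]
        assert np.all(np.diff(vals) > 0)


SIOU_EXAMPLE = (BoundingBox(0.5, 0.5, 0.2, 0.2), BoundingBox(0.6, 0.6, 0.2, 0.2))
# Exact-arithmetic transcription of the cost chain for the pair above
# (theta=4, standard grouping): IoU = 1/7, Lambda = 1, gamma = 1,
# px = py = 1/9, distance = 2 - 2e^{-1/9}, shape = 0.
SIOU_EXPECTED = 0.9623035403284874        # 6/7 + 1 - e^{-1/9}
ASIOU_EXPECTED = 0.9982474958384818       # 1 - (1/7)^3 + (1 - e^{-1/9})^3


class TestSIoUFamily:
    def test_identical_boxes_zero_components(self):
        a = BoundingBox(0.5, 0.5, 0.2, 0.3)
        for fn in (B.siou_loss, B.alpha_siou_loss):
            c = fn(a, a)
            assert c.total == pytest.approx(0.0, abs=1e-6)
            assert c.angle == c.distance == c.shape == 0.0

    def test_frozen_example_values(self):
        c = B.siou_loss(*SIOU_EXAMPLE)
        assert c.iou == pytest.approx(1 / 7, abs=1e-6)
        assert c.angle == pytest.approx(1.0, abs=1e-9)
        assert c.shape == 0.0
        assert c.total == pytest.approx(SIOU_EXPECTED, abs=1e-6)
        ca = B.alpha_siou_loss(*SIOU_EXAMPLE)
        assert ca.total == pytest.approx(ASIOU_EXPECTED, abs=1e-6)

    def test_alpha_one_reduces_to_siou_bitwise(self, rng):
        cfg1 = LossConfig(kind="asiou", alpha=1.0)
        for _ in range(1000):
            a, b = random_boxes(rng, 2)
            s = B.siou_loss(a, b, LossConfig(kind="siou"))
            al = B.alpha_siou_loss(a, b, cfg1)
            assert s.total == al.total  # bit-for-bit

    def test_paper_literal_grouping_adds_angle_term(self):
        std = B.siou_loss(*SIOU_EXAMPLE, LossConfig(kind="siou"))
        lit = B.siou_loss(*SIOU_EXAMPLE, LossConfig(kind="siou", grouping="paper-literal"))
        assert lit.total == pytest.approx(std.total + std.angle / 2, abs=1e-12)

    def test_translation_toward_target_decreases_loss(self):
        """Dense 1-D sweep along the center-connecting line."""
        gt = BoundingBox(0.6, 0.6, 0.2, 0.2)
        ts = np.linspace(0.0, 0.99, 60)
        totals = [B.siou_loss(BoundingBox(0.3 + t * 0.3, 0.3 + t * 0.3, 0.2, 0.2), gt).total
                  for t in ts]
        assert np.all(np.diff(totals) < 0)

    @given(box_strategy(), box_strategy())
    @settings(max_examples=200, deadline=None)
    def test_component_ranges(self, a, b):
        c = B.alpha_siou_loss(a, b)
        assert 0 <= c.iou <= 1
        assert 0 <= c.angle <= 1 + 1e-12
        assert 0 <= c.distance < 2
        assert 0 <= c.shape < 2
        assert c.total >= -1e-9


class TestClassicLossKinds:
    def test_zero_on_identical(self):
        a = BoundingBox(0.5, 0.5, 0.2, 0.3)
        for fn in (B.giou_loss, B.ciou_loss, B.eiou_loss):
            assert fn(a, a) == pytest.approx(0.0, abs=1e-5)

    def test_giou_limit_for_distant_boxes(self):
        a = BoundingBox(0.0, 0.0, 1.0, 1.0)
        vals = [B.giou_loss(a, BoundingBox(d, 0.0, 1.0, 1.0)) for d in (10, 100, 1000)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(2.0, abs=2e-3)

    def test_frozen_random_pair_values(self):
        """Independent transcription of the published formulas for one pair."""
        a = BoundingBox(0.40, 0.45, 0.30, 0.20)
        b = BoundingBox(0.55, 0.50, 0.20, 0.35)
        iou = B.iou(a, b)
        # giou: 1 - IoU + (C - U)/C
        cw, ch = 0.65 - 0.25, 0.675 - 0.325
        inter = (0.55 - 0.45) * (0.55 - 0.35)
        union = 0.06 + 0.07 - inter
        giou_ref = 1 - iou + (cw * ch - union) / (cw * ch)
        assert B.giou_loss(a, b) == pytest.approx(giou_ref, abs=1e-9)
        # eiou: 1 - IoU + d2/c2 + dw2/cw2 + dh2/ch2
        d2 = 0.15**2 + 0.05**2
        eiou_ref = 1 - iou + d2 / (cw**2 + ch**2) + 0.1**2 / cw**2 + 0.15**2 / ch**2
        assert B.eiou_loss(a, b) == pytest.approx(eiou_ref, abs=1e-5)
        # ciou: 1 - IoU + d2/c2 + alpha*v
        v = 4 / math.pi**2 * (math.atan(0.2 / 0.35) - math.atan(0.3 / 0.2)) ** 2
        al = v / (1 - iou + v)
        ciou_ref = 1 - iou + d2 / (cw**2 + ch**2) + al * v
        assert B.ciou_loss(a, b) == pytest.approx(ciou_ref, abs=1e-5)

    def test_all_kinds_nonnegative_random(self, rng):
        for kind in B.LOSS_KINDS:
            cfg = LossConfig(kind=kind)
            a = random_boxes(rng, 500)
            b = random_boxes(rng, 500)
            vals = np.asarray(B.bbox_loss(a, b, cfg))
            assert np.all(vals >= -1e-9), kind


class TestGradients:
    @pytest.mark.parametrize("kind", B.LOSS_KINDS)
    def test_autodiff_matches_finite_differences(self, kind, rng):
        """1e-4 relative agreement at random non-degenerate pairs."""
        cfg = LossConfig(kind=kind)
        for _ in range(20):
            p = np.concatenate([rng.uniform(0.25, 0.75, 2), rng.uniform(0.08, 0.35, 2)])
            t = np.concatenate([rng.uniform(0.25, 0.75, 2), rng.uniform(0.08, 0.35, 2)])
            pt = Tensor(p, requires_grad=True)
            B.bbox_loss(pt, t, cfg).backward()
            g_auto = pt.grad.copy()
            eps = 1e-6
            for i in range(4):
                pp, pm = p.copy(), p.copy()
                pp[i] += eps
                pm[i] -= eps
                fd = (float(np.asarray(B.bbox_loss(pp, t, cfg)))
                      - float(np.asarray(B.bbox_loss(pm, t, cfg)))) / (2 * eps)
                denom = max(abs(fd), 1e-3)
                assert abs(g_auto[i] - fd) / denom < 1e-4, (kind, i)


class TestLossConfig:
    def test_defaults_per_kind(self):
        assert LossConfig(kind="asiou").alpha == 3.0
        assert LossConfig(kind="siou").alpha == 1.0
        assert LossConfig().theta == 4.0

    def test_theta_clamped(self):
        assert LossConfig(theta=10).theta == 6.0
        assert LossConfig(theta=0.5).theta == 2.0

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            LossConfig(kind="diou")
        with pytest.raises(ValueError):
            LossConfig(alpha=0.5)
        with pytest.raises(ValueError):
            LossConfig(grouping="mystery")
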