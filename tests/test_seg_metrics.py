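import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cinefcn.image_io import SHORT_AXIS_SCHEME, SegmentationMap
from cinefcn.seg_metrics import (
    Contour,
    dice,
    evaluate_case,
    extract_contour,
    hausdorff_distance,
    mean_contour_distance,
)

# ---------------------------------------------------------------------------
# Brute-force oracles: direct set counting for Dice, all-pairs distance
# matrices for the contour metrics.  These stay independent of the
# production implementation (which uses KD-trees).
# ---------------------------------------------------------------------------


def oracle_dice(a, b):
    inter = np.sum(a & b)
    total = np.sum(a) + np.sum(b)
    return None if total == 0 else 2.0 * inter / total


def oracle_boundary(mask, spacing):
    pts = []
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            neighbours = [
                mask[r + dr, c + dc] if 0 <= r + dr < rows and 0 <= c + dc < cols else False
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            ]
            if not all(neighbours):
                pts.append((r * spacing[0], c * spacing[1]))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def oracle_distances(pa, pb):
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    mcd = 0.5 * d_ab.mean() + 0.5 * d_ba.mean()
    hd = max(d_ab.max(), d_ba.max())
    return mcd, hd


def random_mask(rng, side):
    m = np.zeros((side, side), dtype=bool)
    n_blobs = rng.integers(1, 4)
    yy, xx = np.mgrid[:side, :side]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(2, side - 2, 2)
        r = rng.uniform(1.5, side / 3)
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return m


class TestDice:
    def test_identity_is_one(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:13, 5:13] = True
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:4, :4] = True
        b[-4:, -4:] = True
        assert dice(a, b) == 0.0

    def test_hand_counted_half_overlap(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :4] = True          # |A| = 4
        b[0, 2:], b[1, :2] = True, True  # |B| = 4, |A n B| = 2
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_flagged_undefined(self):
        z = np.zeros((5, 5), dtype=bool)
        assert dice(z, z) is None

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.ones((3, 3), bool), np.ones((4, 4), bool))

    def test_erosion_monotonicity(self, rng):
        from scipy import ndimage

        ref = random_mask(rng, 24)
        prev = 1.0
        m = ref.copy()
        for _ in range(5):
            m = ndimage.binary_erosion(m)
            if not m.any():
                break
            d = dice(ref, m)
            assert d <= prev
            prev = d


class TestContourExtraction:
    def test_single_pixel_mask(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        c = extract_contour(m, (1.8, 1.8))
        assert len(c) == 1
        np.testing.assert_allclose(c.points_mm[0], [2 * 1.8, 3 * 1.8])

    def test_filled_square_perimeter_count(self):
        m = np.zeros((12, 12), dtype=bool)
        m[1:11, 1:11] = True
        assert len(extract_contour(m)) == 4 * 10 - 4

    def test_full_grid_boundary_is_border(self):
        m = np.ones((6, 6), dtype=bool)
        c = extract_contour(m)
        assert len(c) == 4 * 6 - 4

    def test_empty_mask_empty_contour(self):
        c = extract_contour(np.zeros((4, 4), dtype=bool))
        assert c.is_empty

    def test_matches_oracle_boundary(self, rng):
        for _ in range(20):
            m = random_mask(rng, 16)
            got = extract_contour(m, (1.8, 1.8)).points_mm
            want = oracle_boundary(m, (1.8, 1.8))
            got_set = {tuple(np.round(p, 6)) for p in got}
            want_set = {tuple(np.round(p, 6)) for p in want}
            assert got_set == want_set


class TestContourDistances:
    def test_identical_contours_zero(self):
        c = Contour(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]]))
        assert mean_contour_distance(c, c) == 0.0
        assert hausdorff_distance(c, c) == 0.0

    def test_hand_enumerated_mcd(self):
        ca = Contour(np.array([[0.0, 0.0]]))
        cb = Contour(np.array([[0.0, 0.0], [0.0, 5.0]]))
        # (1/2)*0 + (1/4)*(0 + 5) = 1.25
        assert mean_contour_distance(ca, cb) == pytest.approx(1.25)

    def test_hand_enumerated_hd(self):
        ca = Contour(np.array([[0.0, 0.0]]))
        cb = Contour(np.array([[0.0, 0.0], [0.0, 5.0]]))
        assert hausdorff_distance(ca, cb) == pytest.approx(5.0)

    def test_single_pixels_3px_apart_at_1p8mm(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[2, 2] = True
        b[2, 5] = True
        ca = extract_contour(a, (1.8, 1.8))
        cb = extract_contour(b, (1.8, 1.8))
        assert mean_contour_distance(ca, cb) == pytest.approx(5.4)
        assert hausdorff_distance(ca, cb) == pytest.approx(5.4)

    def test_empty_contour_flagged_undefined(self):
        c = Contour(np.array([[0.0, 0.0]]))
        empty = Contour(np.empty((0, 2)))
        assert mean_contour_distance(c, empty) is None
        assert hausdorff_distance(empty, c) is None


class TestOracleEquivalence:
    def test_exact_match_on_100_random_pairs(self, rng):
        checked = 0
        while checked < 100:
            side = int(rng.integers(6, 33))
            a = random_mask(rng, side)
            b = random_mask(rng, side)
            if not (a.any() and b.any()):
                continue
            sp = (float(rng.uniform(0.5, 3.0)), float(rng.uniform(0.5, 3.0)))
            ca, cb = extract_contour(a, sp), extract_contour(b, sp)
            o_mcd, o_hd = oracle_distances(oracle_boundary(a, sp), oracle_boundary(b, sp))
            assert dice(a, b) == pytest.approx(oracle_dice(a, b), abs=1e-12)
            assert mean_contour_distance(ca, cb) == pytest.approx(o_mcd, abs=1e-9)
            hd = hausdorff_distance(ca, cb)
            assert hd == pytest.approx(o_hd, abs=1e-9)
            assert hd >= mean_contour_distance(ca, cb) - 1e-12
            checked += 1


class TestMetricProperties:
    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask(rng, 20), random_mask(rng, 20)
            assert dice(a, b) == dice(b, a)
            ca, cb = extract_contour(a), extract_contour(b)
            if ca.is_empty or cb.is_empty:
                continue
            assert mean_contour_distance(ca, cb) == pytest.approx(
                mean_contour_distance(cb, ca)
            )
            assert hausdorff_distance(ca, cb) == pytest.approx(
                hausdorff_distance(cb, ca)
            )

    def test_translation_invariance(self, rng):
        a = random_mask(rng, 16)
        b = random_mask(rng, 16)
        pad = 6
        a_t = np.roll(np.pad(a, pad), (3, 2), axis=(0, 1))
        b_t = np.roll(np.pad(b, pad), (3, 2), axis=(0, 1))
        a_p, b_p = np.pad(a, pad), np.pad(b, pad)
        assert dice(a_p, b_p) == dice(a_t, b_t)
        d0 = mean_contour_distance(extract_contour(a_p), extract_contour(b_p))
        d1 = mean_contour_distance(extract_contour(a_t), extract_contour(b_t))
        assert d0 == pytest.approx(d1)
        h0 = hausdorff_distance(extract_contour(a_p), extract_contour(b_p))
        h1 = hausdorff_distance(extract_contour(a_t), extract_contour(b_t))
        assert h0 == pytest.approx(h1)


class TestEvaluateCase:
    def test_identity_case(self, small_case):
        cm = evaluate_case(small_case.truth, small_case.truth)
        for structure in small_case.truth.scheme.foreground():
            sm = cm[structure]
            assert sm.dice == 1.0
            assert sm.mcd_mm == 0.0
            assert sm.hd_mm == 0.0
            assert sm.n_slices > 0

    def test_hd_at_least_mcd(self, small_case):
        from cinefcn.phantom import simulate_observer

        obs = simulate_observer(small_case.truth, 2.0, seed=11)
        cm = evaluate_case(obs, small_case.truth)
        for structure in obs.scheme.foreground():
            sm = cm[structure]
            assert sm.hd_mm >= sm.mcd_mm

    def test_observer_mcd_bounded_by_jitter(self, small_case):
        from cinefcn.phantom import simulate_observer

        mcds = []
        for seed in range(20):
            obs = simulate_observer(small_case.truth, 1.8, seed=seed)
            cm = evaluate_case(obs, small_case.truth, frames=np.array([0]))
            mcds.append(cm["lv_cavity"].mcd_mm)
        mean = float(np.mean(mcds))
        assert 0.0 < mean < 3.6  # within 2x the RMS jitter amplitude

    def test_structure_absent_from_both_is_excluded(self):
        lab = np.zeros((16, 16, 1, 2), dtype=np.uint8)
        lab[4:8, 4:8, 0, :] = 1  # LV cavity only
        seg = SegmentationMap(lab, SHORT_AXIS_SCHEME, (1.8, 1.8, 10.0))
        cm = evaluate_case(seg, seg)
        assert cm["rv_cavity"].dice is None
        assert cm["rv_cavity"].n_slices == 0

    def test_grid_mismatch_rejected(self, small_case):
        lab = np.zeros((8, 8, 1, 2), dtype=np.uint8)
        other = SegmentationMap(lab, SHORT_AXIS_SCHEME, (1.8, 1.8, 10.0))
        with pytest.raises(ValueError):
            evaluate_case(small_case.truth, other)

    def test_no_annotated_frames_rejected(self):
        lab = np.zeros((8, 8, 1, 2), dtype=np.uint8)
        seg = SegmentationMap(lab, SHORT_AXIS_SCHEME, (1.8, 1.8, 10.0))
        with pytest.raises(ValueError):
            evaluate_case(seg, seg)
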