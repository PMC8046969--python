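"""Dice, matching, counts arithmetic, areas, repeatability and STAPLE."""

import math

import numpy as np
import pytest

from somaseg.errors import ContractError, UndefinedMetricError
from somaseg.io_formats import Contour, SomaAnnotation, trace_boundary
from somaseg.metrics import (
    avg_overlapping,
    compile_report,
    dice,
    match_regions,
    precision_from_counts,
    shoelace_area,
    staple,
    union_count,
    yield_rate,
)


def _mask(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


class _FakeDetections:
    """Duck-typed detection container for metric tests."""

    def __init__(self, masks):
        self._masks = masks
        self.detections = [
            type("D", (), {"mask": m, "contour": trace_boundary(m)})()
            for m in masks
        ]

    def masks(self):
        return self._masks


class TestDice:
    def test_identical_masks_give_one(self):
        m = _mask((4, 4), [(0, 0), (1, 1), (2, 2)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = _mask((4, 4), [(0, 0)])
        b = _mask((4, 4), [(3, 3)])
        assert dice(a, b) == 0.0

    def test_hand_counted_example(self):
        # |X|=4, |Y|=6, |X n Y|=3 -> 2*3/10 = 0.6
        x = _mask((4, 4), [(0, 0), (0, 1), (0, 2), (1, 0)])
        y = _mask((4, 4), [(0, 0), (0, 1), (0, 2), (2, 2), (2, 3), (3, 3)])
        assert dice(x, y) == 0.6

    def test_two_empty_masks_are_an_error(self):
        empty = np.zeros((3, 3), dtype=bool)
        with pytest.raises(UndefinedMetricError):
            dice(empty, empty)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            dice(np.ones((2, 2), bool), np.ones((3, 3), bool))

    def test_matches_set_arithmetic_oracle_on_random_small_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.random((4, 4)) < 0.4
            b = rng.random((4, 4)) < 0.4
            sa = {tuple(p) for p in np.argwhere(a)}
            sb = {tuple(p) for p in np.argwhere(b)}
            if not sa and not sb:
                continue
            expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice(a, b) == expected


class TestMatchRegions:
    def _annotations(self, masks):
        return [
            SomaAnnotation(contour=trace_boundary(m), region_id=f"m{i}", mask=m)
            for i, m in enumerate(masks)
        ]

    def test_no_detections_leaves_all_unmatched(self):
        manual = self._annotations([_mask((8, 8), [(1, 1), (1, 2)])])
        table = match_regions(manual, _FakeDetections([]), shape=(8, 8))
        assert table.n_matched == 0
        assert table.rows[0].best_dice == 0.0

    def test_identical_sets_match_perfectly(self):
        masks = [_mask((8, 8), [(1, 1), (1, 2)]), _mask((8, 8), [(5, 5), (6, 5)])]
        manual = self._annotations(masks)
        table = match_regions(manual, _FakeDetections(masks), shape=(8, 8))
        assert table.n_matched == 2
        assert all(r.best_dice == 1.0 for r in table.rows)

    def test_match_requires_dice_strictly_above_threshold(self):
        # one shared pixel out of 1+3: dice = 2/4 = 0.5 exactly -> no match
        manual = self._annotations([_mask((8, 8), [(2, 2)])])
        det = _FakeDetections([_mask((8, 8), [(2, 2), (2, 3), (3, 2)])])
        table = match_regions(manual, det, shape=(8, 8))
        assert table.rows[0].best_dice == 0.5
        assert not table.rows[0].matched

    def test_agrees_with_brute_force_argmax_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            manual_masks = [rng.random((10, 10)) < 0.2 for _ in range(2)]
            det_masks = [rng.random((10, 10)) < 0.2 for _ in range(3)]
            manual_masks = [m for m in manual_masks if m.any()]
            det_masks = [m for m in det_masks if m.any()]
            if not manual_masks or not det_masks:
                continue
            manual = self._annotations(manual_masks)
            table = match_regions(manual, _FakeDetections(det_masks),
                                  shape=(10, 10))
            for row, mmask in zip(table.rows, manual_masks):
                scores = [dice(mmask, d) for d in det_masks]
                assert row.best_dice == max(scores)
                if max(scores) > 0:
                    assert scores[row.best_detected_id] == max(scores)
                assert row.matched == (max(scores) > 0.5)


class TestCountArithmetic:
    def test_yield_rate_printed_example(self):
        # 926 of 965 manually identified neurons detected -> 96%
        assert round(yield_rate(926, 965)) == 96

    def test_yield_rate_bounds(self):
        assert yield_rate(0, 10) == 0.0
        assert yield_rate(10, 10) == 100.0
        with pytest.raises(ValueError):
            yield_rate(1, 0)

    def test_precision_printed_example(self):
        # 345 true positives of 353 detections -> 0.98
        assert round(precision_from_counts(345, 353), 2) == 0.98

    def test_precision_bounds(self):
        assert precision_from_counts(0, 7) == 0.0
        assert precision_from_counts(7, 7) == 1.0
        with pytest.raises(ValueError):
            precision_from_counts(1, 0)

    def test_union_printed_example(self):
        # 315 + 213 - 206 common = 322 unique regions
        assert union_count(315, 213, 206) == 322

    def test_union_edge_cases(self):
        assert union_count(9, 0, 0) == 9
        assert union_count(4, 4, 4) == 4
        with pytest.raises(ValueError):
            union_count(3, 3, 4)


class TestShoelace:
    def test_unit_square(self):
        c = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert shoelace_area(c, 1.0) == 1.0

    def test_right_triangle(self):
        c = Contour(np.array([[0, 0], [4, 0], [0, 3]], float))
        assert shoelace_area(c) == 6.0

    def test_orientation_independent(self):
        v = np.array([[0, 0], [5, 1], [6, 4], [2, 6]], float)
        assert shoelace_area(Contour(v)) == shoelace_area(Contour(v[::-1]))

    def test_pixel_size_scales_quadratically(self):
        c = Contour(np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float))
        assert shoelace_area(c, 0.5) == 4 * 0.25

    def test_area_of_traced_mask_equals_pixel_count(self):
        """Edge-traced contours enclose exactly their pixel count."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = np.zeros((16, 16), dtype=bool)
            r, c = rng.integers(2, 8, 2)
            h, w = rng.integers(2, 7, 2)
            m[r:r + h, c:c + w] = True
            contour = trace_boundary(m)
            assert shoelace_area(contour) == m.sum()


class TestAvgOverlapping:
    def test_five_identical_masks_give_one(self):
        m = _mask((6, 6), [(1, 1), (1, 2), (2, 1)])
        assert avg_overlapping([m] * 5) == 1.0

    def test_hand_computed_mixture(self):
        # intersection 4 px; sizes 4, 8, 8, 8, 8 -> (1 + 4*0.5)/5 = 0.6
        core = [(0, 0), (0, 1), (1, 0), (1, 1)]
        extra = [(3, 3), (3, 4), (4, 3), (4, 4)]
        small = _mask((6, 6), core)
        big = _mask((6, 6), core + extra)
        assert avg_overlapping([small, big, big, big, big]) == 0.6

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(3)
        masks = [rng.random((8, 8)) < 0.6 for _ in range(5)]
        masks = [m | _mask((8, 8), [(0, 0)]) for m in masks]  # non-empty
        value = avg_overlapping(masks)
        assert 0.0 < value <= 1.0
        perm = [masks[i] for i in rng.permutation(5)]
        assert avg_overlapping(perm) == pytest.approx(value, abs=1e-12)

    def test_empty_mask_is_an_error(self):
        m = _mask((4, 4), [(1, 1)])
        with pytest.raises(UndefinedMetricError):
            avg_overlapping([m, np.zeros((4, 4), bool), m, m, m])


def _staple_oracle(decisions, prior, tol, max_iter):
    """Straight-line EM re-implementation used as an independent oracle."""
    D = np.array(decisions, dtype=float)  # raters x pixels
    n_raters = D.shape[0]
    p = [0.9999] * n_raters
    q = [0.9999] * n_raters
    lo, hi = 1e-6, 1 - 1e-6
    for it in range(1, max_iter + 1):
        W = []
        for i in range(D.shape[1]):
            a = prior
            b = 1 - prior
            for j in range(n_raters):
                d = D[j, i]
                a *= p[j] if d else (1 - p[j])
                b *= (1 - q[j]) if d else q[j]
            W.append(a / (a + b))
        new_p, new_q = [], []
        sw = sum(W)
        swc = sum(1 - w for w in W)
        for j in range(n_raters):
            num_p = sum(W[i] for i in range(len(W)) if D[j, i])
            num_q = sum(1 - W[i] for i in range(len(W)) if not D[j, i])
            new_p.append(min(max(num_p / max(sw, lo), lo), hi))
            new_q.append(min(max(num_q / max(swc, lo), lo), hi))
        delta = max(
            max(abs(a - b) for a, b in zip(new_p, p)),
            max(abs(a - b) for a, b in zip(new_q, q)),
        )
        p, q = new_p, new_q
        if delta < tol:
            break
    return np.array(p), np.array(q), np.array([w >= 0.5 for w in W]), it


class TestStaple:
    def test_unanimous_raters_fix_the_consensus(self):
        m = _mask((4, 4), [(1, 1), (1, 2), (2, 1)])
        result = staple([m, m, m])
        assert np.array_equal(result.consensus, m)
        assert (result.sensitivity > 0.99).all()
        assert (result.specificity > 0.99).all()
        assert result.converged

    def test_matches_independent_em_oracle_on_toy_masks(self):
        # 3 raters on a 6-pixel strip
        masks = [
            np.array([[1, 1, 1, 0, 0, 0]], dtype=bool),
            np.array([[0, 1, 1, 1, 0, 0]], dtype=bool),
            np.array([[0, 1, 1, 0, 0, 1]], dtype=bool),
        ]
        prior = float(np.mean([m.mean() for m in masks]))
        result = staple(masks, tol=1e-6, max_iter=100)
        p, q, consensus, _it = _staple_oracle(
            [m.ravel() for m in masks], prior, 1e-6, 100
        )
        assert np.allclose(result.sensitivity, p, atol=1e-9)
        assert np.allclose(result.specificity, q, atol=1e-9)
        assert np.array_equal(result.consensus.ravel(), consensus)

    def test_rater_permutation_permutes_performance(self):
        rng = np.random.default_rng(4)
        masks = [rng.random((5, 5)) < 0.5 for _ in range(3)]
        base = staple(masks)
        swapped = staple([masks[1], masks[0], masks[2]])
        assert np.array_equal(base.consensus, swapped.consensus)
        assert np.allclose(base.sensitivity[[1, 0, 2]], swapped.sensitivity)
        assert np.allclose(base.specificity[[1, 0, 2]], swapped.specificity)

    def test_symmetric_raters_reproduce_majority_vote(self):
        """Raters with identical error structure (p = q across raters)."""
        truth = np.zeros((8, 8), dtype=bool)
        truth[:, :4] = True
        masks = []
        for j in range(5):
            m = truth.copy()
            m[j, 0] = False  # one distinct false negative per rater
            m[j, 7] = True   # one distinct false positive per rater
            masks.append(m)
        majority = np.sum(masks, axis=0) >= 3
        assert np.array_equal(majority, truth)
        result = staple(masks, tol=1e-8, max_iter=200)
        # identical error counts -> identical estimated performance
        assert np.allclose(result.sensitivity, result.sensitivity[0])
        assert np.allclose(result.specificity, result.specificity[0])
        assert np.array_equal(result.consensus, majority)

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(ValueError):
            staple([np.ones((2, 2), bool)])


class TestCompileReport:
    def _pair(self, masks):
        manual = [
            SomaAnnotation(contour=trace_boundary(m), region_id=f"m{i}", mask=m)
            for i, m in enumerate(masks)
        ]
        return manual, _FakeDetections(masks)

    def test_identical_sets_yield_100_dice_1_diff_0(self):
        masks = [_mask((12, 12), [(2, 2), (2, 3), (3, 2), (3, 3)]),
                 _mask((12, 12), [(8, 8), (8, 9)])]
        manual, det = self._pair(masks)
        table = match_regions(manual, det, shape=(12, 12))
        report = compile_report(table, manual, det)
        assert report.yield_rate_pct == 100.0
        assert report.mean_dice == 1.0
        assert report.mean_area_difference == 0.0

    def test_hand_built_area_pairs(self):
        """Two pairs with areas (10, 12) and (20, 18): mean diff 0, r = -1."""
        m1 = np.zeros((20, 20), bool); m1[1:3, 1:6] = True    # 10 px
        d1 = np.zeros((20, 20), bool); d1[1:3, 1:7] = True    # 12 px
        m2 = np.zeros((20, 20), bool); m2[10:14, 1:6] = True  # 20 px
        d2 = np.zeros((20, 20), bool); d2[10:13, 1:7] = True  # 18 px
        manual = [
            SomaAnnotation(contour=trace_boundary(m), region_id=f"m{i}", mask=m)
            for i, m in enumerate([m1, m2])
        ]
        det = _FakeDetections([d1, d2])
        table = match_regions(manual, det, shape=(20, 20))
        report = compile_report(table, manual, det)
        assert report.n_matched == 2
        areas = report.area_pairs
        assert sorted(areas["manual_area_um2"]) == [10.0, 20.0]
        assert sorted(areas["detected_area_um2"]) == [12.0, 18.0]
        assert report.mean_area_difference == 0.0
        assert math.isclose(report.area_correlation, -1.0) or \
            math.isclose(report.area_correlation, 1.0)

    def test_empty_match_table_flags_report(self):
        report = compile_report(
            match_regions([], _FakeDetections([]), shape=(4, 4)),
            [], _FakeDetections([]),
        )
        assert report.empty
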