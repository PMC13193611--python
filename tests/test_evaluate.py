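"""Event matching, detection metrics, lifespan agreement, smoothing."""

import functools
import itertools

import numpy as np
import pytest

from budscan import (DetectorConfig, DivisionTimeline, MAEConfig,
                     detection_scores, lifespan_agreement, match_events,
                     pool_reports, smooth_cycle_trajectory, untrained_baseline)


def _tl(frames, cell="c"):
    return DivisionTimeline(cell_id=cell, event_frames=tuple(frames))


def brute_force_match(gt, pred, max_gap):
    """Exhaustive search over one-to-one assignments (memoized recursion):
    maximize pair count, then minimize total |pred - gt|."""

    @functools.lru_cache(maxsize=None)
    def best(i, used_mask):
        if i == len(gt):
            return (0, 0)
        # option: leave gt[i] unmatched
        cand = [best(i + 1, used_mask)]
        for j, p in enumerate(pred):
            if used_mask & (1 << j):
                continue
            d = abs(p - gt[i])
            if d <= max_gap:
                pairs, cost = best(i + 1, used_mask | (1 << j))
                cand.append((pairs + 1, cost + d))
        return max(cand, key=lambda t: (t[0], -t[1]))

    gt, pred = tuple(gt), tuple(pred)
    return best(0, 0)


class TestMatching:
    def test_partial_match_with_unmatched_on_both_sides(self):
        rep = match_events(_tl([10, 20, 30]), _tl([11, 19, 40]), max_gap=5)
        assert rep.pairs == ((10, 11, 1), (20, 19, -1))
        assert rep.unmatched_gt == (30,)
        assert rep.unmatched_pred == (40,)

    def test_perfect_prediction_all_exact(self):
        rep = match_events(_tl([5, 9, 30]), _tl([5, 9, 30]))
        assert all(e == 0 for *_, e in rep.pairs)
        assert not rep.unmatched_gt and not rep.unmatched_pred

    def test_empty_prediction_leaves_all_gt_unmatched(self):
        rep = match_events(_tl([5, 9]), _tl([]))
        assert rep.pairs == () and rep.unmatched_gt == (5, 9)

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_g, n_p = rng.integers(0, 8, 2)
            gt = sorted(rng.choice(60, n_g, replace=False).tolist())
            pred = sorted(rng.choice(60, n_p, replace=False).tolist())
            rep = match_events(_tl(gt), _tl(pred), max_gap=5)
            pairs, cost = brute_force_match(gt, pred, 5)
            assert len(rep.pairs) == pairs
            assert rep.total_cost == cost

    def test_pairings_respect_max_gap(self):
        rep = match_events(_tl([10]), _tl([16]), max_gap=5)
        assert rep.pairs == ()
        rep = match_events(_tl([10]), _tl([15]), max_gap=5)
        assert rep.pairs == ((10, 15, 5),)


class TestScores:
    def test_formulas_on_known_report(self):
        rep = match_events(_tl([10, 20, 30]), _tl([11, 19, 40]), max_gap=5)
        sc = detection_scores(rep, tolerance=1)
        assert (sc.tp, sc.fp, sc.fn) == (2, 1, 1)
        assert sc.precision == pytest.approx(2 / 3)
        assert sc.recall == pytest.approx(2 / 3)
        assert sc.f1 == pytest.approx(2 / 3)
        assert sc.mean_signed_error == pytest.approx(0.0)
        assert sc.fraction_early == sc.fraction_late

    def test_perfect_prediction_scores_one(self):
        rep = match_events(_tl([5, 9]), _tl([5, 9]))
        sc = detection_scores(rep, tolerance=1)
        assert sc.precision == sc.recall == sc.f1 == 1.0
        assert sc.fraction_exact == 1.0

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            gt = sorted(rng.choice(50, rng.integers(1, 7), replace=False).tolist())
            pred = sorted(rng.choice(50, rng.integers(1, 7), replace=False).tolist())
            sc = detection_scores(match_events(_tl(gt), _tl(pred)), tolerance=1)
            if sc.precision and sc.recall and sc.precision + sc.recall > 0:
                assert sc.f1 == pytest.approx(
                    2 * sc.precision * sc.recall / (sc.precision + sc.recall))

    def test_tolerance_fractions_monotone(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gt = sorted(rng.choice(50, 6, replace=False).tolist())
            pred = sorted((np.asarray(gt) + rng.integers(-3, 4, 6)).clip(0).tolist())
            pred = sorted(set(pred))
            sc = detection_scores(match_events(_tl(gt), _tl(pred)), tolerance=1)
            assert sc.fraction_exact <= sc.fraction_within_1 <= sc.fraction_within_2

    def test_swapping_gt_and_pred_swaps_precision_recall(self):
        gt, pred = [4, 11, 25, 30], [5, 13, 29]
        fwd = detection_scores(match_events(_tl(gt), _tl(pred)), tolerance=1)
        rev = detection_scores(match_events(_tl(pred), _tl(gt)), tolerance=1)
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.mean_signed_error == pytest.approx(-rev.mean_signed_error)

    def test_degenerate_denominators_flagged_not_nan(self):
        sc = detection_scores(match_events(_tl([5]), _tl([])), tolerance=1)
        assert sc.precision is None
        assert "no_predictions" in sc.flags
        assert sc.f1_or_zero() == 0.0

    def test_gt_denominated_fractions(self):
        rep = match_events(_tl([10, 20, 30]), _tl([10]), max_gap=5)
        sc = detection_scores(rep, tolerance=1, denominator="gt")
        assert sc.fraction_exact == pytest.approx(1 / 3)
        assert sc.fraction_unmatched == pytest.approx(2 / 3)

    def test_pooling_reports_adds_counts(self):
        r1 = match_events(_tl([5]), _tl([5]))
        r2 = match_events(_tl([9]), _tl([20]))
        pooled = pool_reports([r1, r2])
        assert pooled.n_gt == 2 and pooled.n_pred == 2
        assert len(pooled.pairs) == 1


class TestLifespan:
    def test_identity_prediction(self):
        recs = [(5, 5), (10, 10), (20, 20), (13, 13)]
        agr = lifespan_agreement(recs)
        assert agr.r_squared == pytest.approx(1.0)
        assert agr.error_sd == 0.0
        assert agr.slope == pytest.approx(1.0)

    def test_constant_offset_keeps_slope_one_zero_sd(self):
        recs = [(5, 7), (10, 12), (20, 22)]
        agr = lifespan_agreement(recs)
        assert agr.slope == pytest.approx(1.0)
        assert agr.error_sd == 0.0
        assert agr.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.integers(3, 30, 40)
        p = g + rng.integers(-4, 5, 40)
        agr = lifespan_agreement(list(zip(g, p)))
        # independent closed-form OLS via the normal equations
        X = np.stack([g.astype(float), np.ones_like(g, dtype=float)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ p.astype(float))
        resid = p - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((p - p.mean()) ** 2).sum()
        assert agr.slope == pytest.approx(beta[0], abs=1e-10)
        assert agr.intercept == pytest.approx(beta[1], abs=1e-10)
        assert agr.r_squared == pytest.approx(r2, abs=1e-10)

    def test_constant_gt_rejected(self):
        with pytest.raises(ValueError):
            lifespan_agreement([(5, 4), (5, 6), (5, 5)])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            lifespan_agreement([(5, 5), (6, 6)])


class TestSmoothing:
    def test_low_order_polynomial_reproduced(self):
        x = np.linspace(0, 100, 51)
        y = 0.02 * x ** 2 - x + 3
        pts = list(zip(x, y))
        xs, smoothed = smooth_cycle_trajectory(pts, window=11, polyorder=2,
                                               bin_width=None)
        np.testing.assert_allclose(smoothed, 0.02 * xs ** 2 - xs + 3, atol=1e-8)

    def test_constant_input_constant_output(self):
        pts = [(p, 4.0) for p in np.linspace(0, 100, 40)]
        _, smoothed = smooth_cycle_trajectory(pts)
        np.testing.assert_allclose(smoothed, 4.0)

    def test_output_length_equals_input_length(self):
        rng = np.random.default_rng(4)
        pts = list(zip(np.linspace(0, 100, 60), rng.random(60)))
        xs, smoothed = smooth_cycle_trajectory(pts, bin_width=None)
        assert len(xs) == len(smoothed) == 60

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_cycle_trajectory([(0, 1), (50, 2), (100, 3)], window=11)


def test_untrained_baseline_deterministic(rng):
    mae_cfg = MAEConfig(encoder_dim=32, encoder_depth=1, encoder_heads=2,
                        decoder_dim=16, decoder_depth=1, decoder_heads=2, seed=0)
    det_cfg = DetectorConfig(temporal_dim=32, temporal_depth=1, temporal_heads=2, seed=0)
    movies = {"m": rng.random((20, 64, 64)).astype(np.float32)}
    a = untrained_baseline(mae_cfg, det_cfg, movies, seed=5)
    b = untrained_baseline(mae_cfg, det_cfg, movies, seed=5)
    np.testing.assert_array_equal(a["m"].probs, b["m"].probs)
    assert len(a["m"].probs) == 20
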