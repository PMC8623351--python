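"""Recommender: thresholds, lexicographic ranking, cost function, therapy rule."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tscscal import (
    AnalysisConfig,
    ProtocolConfig,
    RatingLabel,
    ResponseFeatures,
    amplitude_threshold,
    all_thresholds,
    cost_scores,
    rank_pairs,
    recommend,
    therapy_amplitude,
)
from tscscal.evaluate import RatingCell, RatingMatrix

MUSCLES = ("LQ", "LTS", "RQ", "RTS")

FEATS = {
    RatingLabel.REFLEX: ResponseFeatures(200.0, 20.0, 0.9),
    RatingLabel.M_WAVE: ResponseFeatures(200.0, 160.0, 0.2),
    RatingLabel.NO_RESPONSE: ResponseFeatures(10.0, 10.0, 0.0),
    RatingLabel.INVALID: None,
}


def matrix_from_labels(labels: dict, features: dict | None = None) -> RatingMatrix:
    """labels: (muscle, n, I) -> RatingLabel; features optionally override."""
    cells = {}
    for key, lab in labels.items():
        feats = (features or {}).get(key, FEATS[lab])
        cells[key] = RatingCell(lab, feats)
    return RatingMatrix(cells, MUSCLES)


def grid_labels(positions, amplitudes, default=RatingLabel.NO_RESPONSE):
    return {(m, n, I): default for m in MUSCLES for n in positions for I in amplitudes}


# -- amplitude threshold -----------------------------------------------------


def test_threshold_is_first_green(protocol):
    labels = grid_labels([2], protocol.amplitude_grid_mA)
    labels[("LQ", 2, 40.0)] = RatingLabel.REFLEX
    labels[("RQ", 2, 45.0)] = RatingLabel.REFLEX
    rating = matrix_from_labels(labels)
    assert amplitude_threshold(rating, 2).threshold_mA == 40.0


def test_threshold_absent_without_green(protocol):
    rating = matrix_from_labels(grid_labels([4], protocol.amplitude_grid_mA))
    assert amplitude_threshold(rating, 4).threshold_mA is None


def test_threshold_minimum_of_two_greens():
    labels = grid_labels([1], [25.0, 30.0])
    labels[("LQ", 1, 25.0)] = RatingLabel.REFLEX
    labels[("RQ", 1, 30.0)] = RatingLabel.REFLEX
    assert amplitude_threshold(matrix_from_labels(labels), 1).threshold_mA == 25.0


# -- ranking -----------------------------------------------------------------


def set_greens(labels, n, I, count):
    for m in MUSCLES[:count]:
        labels[(m, n, I)] = RatingLabel.REFLEX


def test_green_count_dominates_threshold_distance():
    labels = grid_labels([1, 2], [20.0, 25.0])
    set_greens(labels, 1, 20.0, 2)  # I' = 20
    set_greens(labels, 1, 25.0, 4)  # 4 greens at I - I' = 5
    set_greens(labels, 2, 20.0, 3)  # 3 greens at I - I' = 0
    rating = matrix_from_labels(labels)
    ranks = rank_pairs(rating, all_thresholds(rating))
    assert (ranks[0].electrode_position, ranks[0].amplitude_mA) == (1, 25.0)
    assert (ranks[1].electrode_position, ranks[1].amplitude_mA) == (2, 20.0)


def test_smaller_threshold_distance_wins_at_equal_greens():
    labels = grid_labels([1, 2], [20.0, 30.0])
    set_greens(labels, 1, 20.0, 3)  # I - I' = 0
    set_greens(labels, 2, 20.0, 2)
    set_greens(labels, 2, 30.0, 3)  # I - I' = 10
    rating = matrix_from_labels(labels)
    ranks = rank_pairs(rating, all_thresholds(rating))
    three_green = [r for r in ranks if r.green_count == 3]
    assert (three_green[0].electrode_position, three_green[0].amplitude_mA) == (1, 20.0)


def _random_matrix(rng, positions=(1, 2, 3), amplitudes=(10.0, 20.0, 30.0, 40.0)):
    labels = {}
    for n in positions:
        for I in amplitudes:
            for m in MUSCLES:
                labels[(m, n, I)] = rng.choice(
                    [RatingLabel.NO_RESPONSE, RatingLabel.REFLEX,
                     RatingLabel.M_WAVE, RatingLabel.INVALID],
                    p=[0.4, 0.35, 0.15, 0.1],
                )
    return matrix_from_labels(labels)


def oracle_rank(rating: RatingMatrix, min_greens=2):
    """Brute-force 4-level lexicographic sort of all qualifying pairs."""
    thr = all_thresholds(rating)
    rows = []
    for n in rating.positions:
        for I in rating.amplitudes:
            g = rating.green_count(n, I)
            if g >= min_greens:
                rows.append((-g, I - thr[n], I, n))
    rows.sort()
    return [(n, I) for (_, _, I, n) in rows]


def test_rank_order_equals_bruteforce_oracle():
    rng = np.random.default_rng(777)
    for _ in range(300):
        rating = _random_matrix(rng)
        ranks = rank_pairs(rating, all_thresholds(rating))
        got = [(r.electrode_position, r.amplitude_mA) for r in ranks]
        assert got == oracle_rank(rating)
        assert [r.rank for r in ranks] == list(range(1, len(ranks) + 1))
        assert all(r.green_count >= 2 for r in ranks)


def test_removing_a_position_never_hurts_others():
    rng = np.random.default_rng(42)
    for _ in range(50):
        rating = _random_matrix(rng)
        full = {(r.electrode_position, r.amplitude_mA): r.rank
                for r in rank_pairs(rating, all_thresholds(rating))}
        drop = 2
        reduced_cells = {k: v for k, v in rating.cells.items() if k[1] != drop}
        reduced = RatingMatrix(reduced_cells, rating.muscles)
        for r in rank_pairs(reduced, all_thresholds(reduced)):
            key = (r.electrode_position, r.amplitude_mA)
            assert r.rank <= full[key]


# -- cost function -----------------------------------------------------------


def test_cost_upper_bound_at_own_maxima():
    labels = grid_labels([1], [30.0])
    feats = {}
    for m in MUSCLES:
        labels[(m, 1, 30.0)] = RatingLabel.REFLEX
        feats[(m, 1, 30.0)] = ResponseFeatures(300.0, 0.0, 1.0)
    values, norms = cost_scores(matrix_from_labels(labels, feats))
    assert values[0].J == pytest.approx(1.0)
    assert all(v == 300.0 for v in norms.values())


def test_cost_zero_for_gray_matrix(protocol):
    rating = matrix_from_labels(grid_labels([1, 2], [10.0, 20.0]))
    values, _ = cost_scores(rating)
    assert all(v.J == pytest.approx(0.0, abs=1e-12) for v in values)


def test_cost_hand_computed_grid():
    # 2 positions x 2 amplitudes, amplitudes/suppressions chosen by hand:
    #   norms: LQ max amp1 = 400, RQ = 200; LTS/RTS never respond (norm 10)
    labels = grid_labels([1, 2], [10.0, 20.0])
    feats = {}
    spec = {
        (1, 10.0): {"LQ": (100.0, 0.5), "RQ": (100.0, 1.0)},
        (1, 20.0): {"LQ": (400.0, 0.25), "RQ": (200.0, 0.5)},
        (2, 10.0): {"LQ": (200.0, 1.0)},
        (2, 20.0): {"LQ": (300.0, 0.8), "RQ": (100.0, 0.2)},
    }
    for (n, I), per in spec.items():
        for m, (a1, sup) in per.items():
            labels[(m, n, I)] = RatingLabel.REFLEX
            feats[(m, n, I)] = ResponseFeatures(a1, a1 * (1 - sup), sup)
    values, norms = cost_scores(matrix_from_labels(labels, feats))
    assert norms["LQ"] == 400.0 and norms["RQ"] == 200.0
    j = {(v.electrode_position, v.amplitude_mA): v.J for v in values}
    # spreadsheet-style recomputation (gray cells contribute amp1=10/norm * 0)
    assert j[(1, 10.0)] == pytest.approx((100 / 400 * 0.5 + 100 / 200 * 1.0) / 4)
    assert j[(1, 20.0)] == pytest.approx((400 / 400 * 0.25 + 200 / 200 * 0.5) / 4)
    assert j[(2, 10.0)] == pytest.approx((200 / 400 * 1.0 + 10 / 200 * 0.0) / 4)
    assert j[(2, 20.0)] == pytest.approx((300 / 400 * 0.8 + 100 / 200 * 0.2) / 4)


@given(c=st.floats(0.1, 10.0))
def test_cost_invariant_to_per_muscle_scaling(c):
    labels = grid_labels([1], [10.0, 20.0])
    feats, feats_scaled = {}, {}
    rng = np.random.default_rng(5)
    for I in (10.0, 20.0):
        for m in MUSCLES:
            a1 = float(rng.uniform(60, 300))
            sup = float(rng.uniform(0, 1))
            labels[(m, 1, I)] = RatingLabel.REFLEX
            feats[(m, 1, I)] = ResponseFeatures(a1, a1 * (1 - sup), sup)
            scale = c if m == "LQ" else 1.0
            feats_scaled[(m, 1, I)] = ResponseFeatures(scale * a1, scale * a1 * (1 - sup), sup)
    v1, _ = cost_scores(matrix_from_labels(labels, feats))
    v2, _ = cost_scores(matrix_from_labels(labels, feats_scaled))
    for a, b in zip(v1, v2):
        assert a.J == pytest.approx(b.J)


# -- therapy amplitude and recommendation ------------------------------------


def test_therapy_rule_worked_example(protocol, cfg):
    assert therapy_amplitude(40.0, protocol, cfg) == 35.0  # 0.9*40 = 36 -> grid floor


def test_therapy_rule_rounding_none(protocol):
    cfg = AnalysisConfig(rounding="none")
    assert therapy_amplitude(20.0, protocol, cfg) == pytest.approx(18.0)


@given(thr=st.sampled_from([10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]))
def test_therapy_always_subthreshold(thr):
    protocol, cfg = ProtocolConfig(), AnalysisConfig()
    assert therapy_amplitude(thr, protocol, cfg) < thr


def test_recommend_full_flow(protocol, cfg):
    labels = grid_labels([1, 2, 3, 4], protocol.amplitude_grid_mA)
    set_greens(labels, 2, 40.0, 1)  # first green at 40 -> I'(2) = 40
    set_greens(labels, 2, 45.0, 4)
    set_greens(labels, 3, 60.0, 2)
    rating = matrix_from_labels(labels)
    rec = recommend(rating, protocol, cfg)
    assert rec.ranking.electrode_position == 2
    assert rec.ranking.threshold_mA == 40.0
    assert rec.ranking.therapy_amplitude_mA == 35.0
    assert rec.cost.electrode_position == 2
    assert rec.agree is True
    assert rec.rank_table[0].green_count == 4


def test_recommend_absent_without_candidates(protocol, cfg):
    labels = grid_labels([1, 2], protocol.amplitude_grid_mA)
    set_greens(labels, 1, 30.0, 1)  # single green: below the 2-green minimum
    rec = recommend(matrix_from_labels(labels), protocol, cfg)
    assert rec.ranking.electrode_position is None
    assert rec.cost.electrode_position is None
    assert "at least 2" in rec.ranking.reason
    assert rec.rank_table == ()
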