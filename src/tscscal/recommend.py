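"""Electrode-position and therapy-amplitude recommendation.

Two independent methods run on the rating matrix:

*Ranking approach* — candidate (electrode, amplitude) pairs must show
reflex responses (green) in at least two of the four muscles, then are
ordered by (1) most green labels, (2) smallest difference between the
amplitude I and the electrode's amplitude threshold I' (the lowest
amplitude with a first green at that electrode), (3) lowest amplitude I.
Rank 1 is best.

*Cost-function approach* — each pair is scored by

    J(n, I) = (1/M) * sum_i  amp1_i(n, I) / max_amp1_i * sup_i(n, I)

where max_amp1_i is the largest first-response amplitude observed anywhere
for muscle i, so J in [0, 1] favors positions with large, strongly
suppressed (reflex-like) responses in all muscles.  The electrode of the
globally maximal J is selected.

Both methods suggest a sub-threshold therapy amplitude of 90% of the
selected electrode's threshold I', floored to the amplitude grid (e.g.
0.9 * 40 mA = 36 mA -> 35 mA on a 5 mA grid), guaranteeing stimulation
below the reflex threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .config import AnalysisConfig, ProtocolConfig
from .evaluate import RatingLabel, RatingMatrix


@dataclass(frozen=True)
class ElectrodeThreshold:
    electrode_position: int
    threshold_mA: Optional[float]  # None when no green at this electrode


@dataclass(frozen=True)
class RankEntry:
    electrode_position: int
    amplitude_mA: float
    rank: int
    green_count: int


@dataclass(frozen=True)
class CostValue:
    electrode_position: int
    amplitude_mA: float
    J: float


@dataclass(frozen=True)
class MethodResult:
    method: str  # "ranking" | "cost"
    electrode_position: Optional[int]
    threshold_mA: Optional[float]
    therapy_amplitude_mA: Optional[float]
    reason: Optional[str] = None


@dataclass(frozen=True)
class Recommendation:
    ranking: MethodResult
    cost: MethodResult
    agree: Optional[bool]  # None when either method abstained
    rank_table: tuple[RankEntry, ...]
    cost_table: tuple[CostValue, ...]
    thresholds: Mapping[int, Optional[float]]
    normalizers_uV: Mapping[str, float]


def amplitude_threshold(rating: RatingMatrix, n: int) -> ElectrodeThreshold:
    """Lowest amplitude with a green label in any muscle at electrode *n*."""
    greens = sorted(
        I
        for (m, pos, I), cell in rating.cells.items()
        if pos == n and cell.label is RatingLabel.REFLEX
    )
    return ElectrodeThreshold(n, greens[0] if greens else None)


def all_thresholds(rating: RatingMatrix) -> dict[int, Optional[float]]:
    return {n: amplitude_threshold(rating, n).threshold_mA for n in rating.positions}


def rank_pairs(
    rating: RatingMatrix,
    thresholds: Mapping[int, Optional[float]],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[RankEntry]:
    """Lexicographic ranking of candidate (electrode, amplitude) pairs.

    Only pairs with >= `min_green_muscles` greens qualify.  Residual ties
    after the amplitude criteria are broken toward the more caudal (lower)
    electrode position for determinism.
    """
    pairs = sorted({(n, I) for (_, n, I) in rating.cells})
    candidates = []
    for n, I in pairs:
        g = rating.green_count(n, I)
        if g < cfg.min_green_muscles:
            continue
        thr = thresholds.get(n)
        # a candidate has >= 2 greens, hence its electrode has a threshold
        assert thr is not None
        candidates.append((n, I, g, I - thr))
    candidates.sort(key=lambda c: (-c[2], c[3], c[1], c[0]))
    return [
        RankEntry(n, I, rank, g)
        for rank, (n, I, g, _) in enumerate(candidates, start=1)
    ]


def cost_scores(rating: RatingMatrix) -> tuple[list[CostValue], dict[str, float]]:
    """Normalized cost J for every evaluated pair, plus the per-muscle
    normalizers (maximal amp1 found in each muscle).

    Invalid cells (and muscles whose normalizer is 0) contribute 0.
    """
    normalizers: dict[str, float] = {m: 0.0 for m in rating.muscles}
    for (m, _, _), cell in rating.cells.items():
        if cell.features is not None:
            normalizers[m] = max(normalizers[m], cell.features.amp1_uV)
    pairs = sorted({(n, I) for (_, n, I) in rating.cells})
    values = []
    n_muscles = len(rating.muscles)
    for n, I in pairs:
        total = 0.0
        for m in rating.muscles:
            cell = rating.cells.get((m, n, I))
            if cell is None or cell.features is None or normalizers[m] <= 0:
                continue
            total += cell.features.amp1_uV / normalizers[m] * cell.features.suppression
        values.append(CostValue(n, I, total / n_muscles))
    return values, normalizers


def therapy_amplitude(
    threshold_mA: float,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> float:
    """Sub-threshold amplitude: therapy_fraction * I', floored to the grid."""
    target = cfg.therapy_fraction * threshold_mA
    if cfg.rounding == "none":
        return target
    below = [a for a in protocol.amplitude_grid_mA if a <= target]
    return max(below) if below else target


def recommend(
    rating: RatingMatrix,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> Recommendation:
    """Run both recommendation methods on a rating matrix."""
    thresholds = all_thresholds(rating)
    ranks = rank_pairs(rating, thresholds, cfg)
    costs, normalizers = cost_scores(rating)

    if not ranks:
        reason = "no (electrode, amplitude) pair with at least %d reflex responses" % (
            cfg.min_green_muscles
        )
        absent_rank = MethodResult("ranking", None, None, None, reason)
        absent_cost = MethodResult("cost", None, None, None, reason)
        return Recommendation(
            absent_rank, absent_cost, None, (), tuple(costs), thresholds, normalizers
        )

    best = ranks[0]
    n_rank = best.electrode_position
    thr_rank = thresholds[n_rank]
    assert thr_rank is not None
    ranking_result = MethodResult(
        "ranking", n_rank, thr_rank, therapy_amplitude(thr_rank, protocol, cfg)
    )

    # globally maximal J; ties toward lower amplitude then lower position
    best_cost = max(costs, key=lambda c: (c.J, -c.amplitude_mA, -c.electrode_position))
    n_cost = best_cost.electrode_position
    thr_cost = thresholds.get(n_cost)
    if thr_cost is None:
        cost_result = MethodResult(
            "cost", n_cost, None, None,
            "selected electrode has no reflex threshold (no green label)",
        )
    else:
        cost_result = MethodResult(
            "cost", n_cost, thr_cost, therapy_amplitude(thr_cost, protocol, cfg)
        )

    agree: Optional[bool]
    if cost_result.electrode_position is None or ranking_result.electrode_position is None:
        agree = None
    else:
        agree = cost_result.electrode_position == ranking_result.electrode_position

    return Recommendation(
        ranking_result,
        cost_result,
        agree,
        tuple(ranks),
        tuple(costs),
        thresholds,
        normalizers,
    )
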