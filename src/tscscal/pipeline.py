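"""End-to-end calibration: raw sweeps in, recommendation out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import AnalysisConfig, ProtocolConfig
from .evaluate import RatingMatrix, build_rating_matrix
from .preprocess import AveragedResponse, NoiseProfile, preprocess_session
from .recommend import Recommendation, recommend
from .session import SweepRecord
from .sync import AlignedSweep, synchronize_session


@dataclass(frozen=True)
class CalibrationResult:
    rating: RatingMatrix
    recommendation: Recommendation
    noise: NoiseProfile
    responses: Sequence[AveragedResponse]
    dispositions: Mapping[tuple[int, float, int], str]  # (n, I, j) -> sweep status

    @property
    def invalid_cell_ratio(self) -> float:
        return self.rating.invalid_ratio()

    def disposition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for status in self.dispositions.values():
            counts[status] = counts.get(status, 0) + 1
        return counts


def calibrate_session(
    records: Sequence[SweepRecord],
    protocol: ProtocolConfig = ProtocolConfig(),
    cfg: AnalysisConfig = AnalysisConfig(),
) -> CalibrationResult:
    """Run synchronization, preprocessing, rating and recommendation."""
    aligned: list[AlignedSweep] = synchronize_session(records, protocol, cfg)
    responses, noise, filtered = preprocess_session(aligned, protocol, cfg)
    rating = build_rating_matrix(responses, noise, protocol, cfg)
    rec = recommend(rating, protocol, cfg)
    dispositions = {sw.source.key: sw.status for sw in aligned}
    return CalibrationResult(rating, rec, noise, responses, dispositions)
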