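"""Response feature extraction and the four-color rating system.

For each averaged response the peak-to-peak amplitudes of the reactions to
the first and second pulse of the double stimulus are measured in the
10-45 ms windows after the respective stimuli (amp1, amp2, in uV).  The
paired-pulse suppression

    sup = clip(1 - amp2 / amp1, 0, 1)

exploits post-activation depression: a posterior root-muscle (PRM) reflex
is strongly suppressed on the second pulse delivered 50 ms later, while a
direct motor response (M-wave) is not.  Each (muscle, electrode, amplitude)
cell is then classified:

    gray    no response      amp1 <= 6x base noise  OR  amp1 <= 50 uV
    green   reflex           amp1 above both gates  AND sup > 0.60
    yellow  presumed M-wave  amp1 above both gates  AND sup <= 0.60
    red     invalid          no similar repetitions were available

The rules are exhaustive and mutually exclusive over (amp1, sup, validity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import AnalysisConfig, ProtocolConfig
from .preprocess import AveragedResponse, NoiseProfile, PreprocessError


class RatingLabel(enum.Enum):
    NO_RESPONSE = "no_response"
    REFLEX = "reflex"
    M_WAVE = "m_wave"
    INVALID = "invalid"

    @property
    def color(self) -> str:
        return _COLORS[self]

    @classmethod
    def from_color(cls, color: str) -> "RatingLabel":
        return _FROM_COLOR[color]


_COLORS = {
    RatingLabel.NO_RESPONSE: "gray",
    RatingLabel.REFLEX: "green",
    RatingLabel.M_WAVE: "yellow",
    RatingLabel.INVALID: "red",
}
_FROM_COLOR = {v: k for k, v in _COLORS.items()}


@dataclass(frozen=True)
class ResponseFeatures:
    """amp1/amp2 peak-to-peak amplitudes (uV) and the suppression ratio."""

    amp1_uV: float
    amp2_uV: float
    suppression: float
    suppression_defined: bool = True

    def __post_init__(self) -> None:
        if self.amp1_uV < 0 or self.amp2_uV < 0:
            raise ValueError("peak-to-peak amplitudes must be nonnegative")
        if not (0.0 <= self.suppression <= 1.0):
            raise ValueError("suppression must lie in [0, 1]")


@dataclass(frozen=True)
class RatingCell:
    label: RatingLabel
    features: Optional[ResponseFeatures]
    reason: Optional[str] = None


@dataclass(frozen=True)
class RatingMatrix:
    """Map (muscle, electrode position, amplitude) -> rating cell."""

    cells: Mapping[tuple[str, int, float], RatingCell]
    muscles: tuple[str, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted({k[1] for k in self.cells}))

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(sorted({k[2] for k in self.cells}))

    def label(self, muscle: str, n: int, I: float) -> RatingLabel:
        return self.cells[(muscle, n, I)].label

    def features(self, muscle: str, n: int, I: float) -> Optional[ResponseFeatures]:
        return self.cells[(muscle, n, I)].features

    def green_count(self, n: int, I: float) -> int:
        return sum(
            1
            for m in self.muscles
            if (m, n, I) in self.cells and self.cells[(m, n, I)].label is RatingLabel.REFLEX
        )

    def invalid_ratio(self) -> float:
        """Fraction of evaluated cells marked invalid (session QC metric)."""
        total = len(self.cells)
        if total == 0:
            return 0.0
        bad = sum(1 for c in self.cells.values() if c.label is RatingLabel.INVALID)
        return bad / total


def peak_to_peak(
    avg: AveragedResponse,
    muscle: str,
    which: str,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> float:
    """max - min of the averaged series in the 10-45 ms window after the
    first (`which='first'`) or second (`which='second'`) stimulus."""
    if which not in ("first", "second"):
        raise ValueError("which must be 'first' or 'second'")
    if not avg.valid.get(muscle, False) or avg.series[muscle] is None:
        raise PreprocessError(f"no valid averaged series for muscle {muscle}")
    shift = protocol.inter_pulse_interval_ms if which == "second" else 0.0
    lo, hi = cfg.amp_window_ms
    sl = avg.window_slice(lo + shift, hi + shift)
    seg = avg.series[muscle][sl]
    return float(np.max(seg) - np.min(seg))


def suppression(amp1_uV: float, amp2_uV: float) -> float:
    """Paired-pulse suppression 1 - amp2/amp1, clipped to [0, 1].

    amp1 = 0 carries no assessable response, so no suppression (0.0) is
    reported; callers can detect the case via amp1 itself.
    """
    if amp1_uV < 0 or amp2_uV < 0:
        raise ValueError("amplitudes must be nonnegative")
    if amp1_uV == 0:
        return 0.0
    return float(np.clip(1.0 - amp2_uV / amp1_uV, 0.0, 1.0))


def extract_features(
    avg: AveragedResponse,
    muscle: str,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> ResponseFeatures:
    amp1 = peak_to_peak(avg, muscle, "first", protocol, cfg)
    amp2 = peak_to_peak(avg, muscle, "second", protocol, cfg)
    return ResponseFeatures(amp1, amp2, suppression(amp1, amp2), suppression_defined=amp1 > 0)


def classify(
    features: Optional[ResponseFeatures],
    noise_level_uV: float,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> RatingLabel:
    """Apply the rating rules; ``features=None`` marks an invalid cell."""
    if features is None:
        return RatingLabel.INVALID
    responded = (
        features.amp1_uV > cfg.noise_sd_factor * noise_level_uV
        and features.amp1_uV > cfg.min_amp_uV
    )
    if not responded:
        return RatingLabel.NO_RESPONSE
    if features.suppression > cfg.suppression_threshold:
        return RatingLabel.REFLEX
    return RatingLabel.M_WAVE


def build_rating_matrix(
    responses: Sequence[AveragedResponse],
    noise: NoiseProfile,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> RatingMatrix:
    """Label every evaluated (muscle, electrode, amplitude) cell."""
    cells: dict[tuple[str, int, float], RatingCell] = {}
    for avg in responses:
        for muscle in protocol.muscle_labels:
            key = (muscle, avg.electrode_position, avg.amplitude_mA)
            if avg.valid.get(muscle, False):
                feats = extract_features(avg, muscle, protocol, cfg)
                cells[key] = RatingCell(classify(feats, noise[muscle], cfg), feats)
            else:
                cells[key] = RatingCell(RatingLabel.INVALID, None, avg.reasons.get(muscle))
    return RatingMatrix(cells, tuple(protocol.muscle_labels))
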