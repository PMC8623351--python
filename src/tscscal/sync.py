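"""Stimulus-artifact detection and sweep alignment.

Raw sweeps are recorded by two wireless sensors (one per limb) that are not
hardware-synchronized to the stimulator, so the time of the first stimulus
must be recovered from the stimulation artifact itself.  Detection runs on
the two quadriceps channels (LQ, RQ): the raw signal is double-differentiated
with a discrete Laplacian,

    emg_delta[k] = 4 * (x[k-1] - 2*x[k] + x[k+1]),

and a sample ``t*`` is an artifact candidate when

    C1: |emg_delta[t*]|        >  3 * SD(emg_delta over the tail window)
    C2: |emg_delta[t* + p]|    >  3 * SD(...)        (p = inter-pulse samples,
                                                      the second pulse)
    C3: |emg_delta[t* + 2p]|   <= 3 * SD(...)        (rejects periodic hits)
    C4: the median-free raw signal changes sign at t* against its previous
        or next sample.

The tail window is the late, response-free part of the raw sweep (0-based
samples 299..599 at 1 kHz); SD is the sample standard deviation (ddof=1).
The earliest candidate within the search interval (0-based samples 9..199)
on either quadriceps channel becomes t = 0, and all channels of both sensor
groups are cropped to -30..300 ms (331 samples at 1 kHz).

A sweep in which C1 never holds on either detection channel contains no
artifact at all and is declared *baseline* (its first 331 samples are kept
to characterize noise); a sweep where C1 fires somewhere but no sample
satisfies all four conditions is *discarded*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .config import AnalysisConfig, ProtocolConfig
from .session import SweepRecord

DETECTION_CHANNELS = ("LQ", "RQ")

ALIGNED = "aligned"
BASELINE = "baseline"
DISCARDED = "discarded"


class DegenerateSweepError(ValueError):
    """Sweep too short for the requested operation."""


@dataclass(frozen=True)
class AlignedSweep:
    """A sweep re-timed so that the first stimulus is at t = 0.

    ``samples`` hold the cropped channels (length = crop window + 1 sample);
    ``t0_index`` is the array index of t = 0.  Baseline sweeps keep their
    first ``len(crop)`` samples on a nominal time axis with the same
    ``t0_index`` (there is no stimulus, the axis only serves windowing).
    Discarded sweeps carry no samples.
    """

    source: SweepRecord
    status: str
    onset_index: Optional[int]
    samples: Optional[Mapping[str, np.ndarray]] = field(repr=False, default=None)
    t0_index: int = 0
    sampling_rate_hz: float = 1000.0

    @property
    def electrode_position(self) -> int:
        return self.source.electrode_position

    @property
    def amplitude_mA(self) -> float:
        return self.source.amplitude_mA

    @property
    def repetition(self) -> int:
        return self.source.repetition

    def n_samples(self) -> int:
        if self.samples is None:
            return 0
        return len(next(iter(self.samples.values())))

    def time_ms(self) -> np.ndarray:
        """Time axis in ms, t = 0 at the first stimulus."""
        return (np.arange(self.n_samples()) - self.t0_index) * 1000.0 / self.sampling_rate_hz

    def window_slice(self, t_lo_ms: float, t_hi_ms: float) -> slice:
        """Array slice covering the closed interval [t_lo, t_hi] ms."""
        fs = self.sampling_rate_hz
        lo = self.t0_index + int(round(t_lo_ms * fs / 1000.0))
        hi = self.t0_index + int(round(t_hi_ms * fs / 1000.0))
        if lo < 0 or hi >= self.n_samples():
            raise DegenerateSweepError(
                f"window [{t_lo_ms}, {t_hi_ms}] ms outside aligned sweep"
            )
        return slice(lo, hi + 1)

    def replace_samples(self, samples: Mapping[str, np.ndarray]) -> "AlignedSweep":
        return AlignedSweep(
            source=self.source,
            status=self.status,
            onset_index=self.onset_index,
            samples=samples,
            t0_index=self.t0_index,
            sampling_rate_hz=self.sampling_rate_hz,
        )


def double_difference(x: np.ndarray) -> np.ndarray:
    """Scaled discrete Laplacian, the detection signal for artifacts.

    Returns ``4 * (x[k-1] - 2 x[k] + x[k+1])`` with the two edge samples
    (no valid stencil) set to 0; output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DegenerateSweepError("double_difference needs at least 3 samples")
    d = np.zeros_like(x)
    d[1:-1] = 4.0 * (x[:-2] - 2.0 * x[1:-1] + x[2:])
    return d


@dataclass(frozen=True)
class DetectionResult:
    status: str  # aligned | baseline | discarded
    onset_index: Optional[int]
    channel: Optional[str]  # detection channel that provided the onset
    per_channel: Mapping[str, Optional[int]]


def _channel_candidates(
    raw: np.ndarray, protocol: ProtocolConfig, cfg: AnalysisConfig
) -> tuple[np.ndarray, bool]:
    """Candidate onsets for one detection channel.

    Returns (sorted candidate indices within the search interval,
    C1-holds-anywhere flag over the whole sweep).
    """
    n = raw.size
    delta = double_difference(raw)
    t0, t1 = cfg.tail_window_samples
    tail = delta[t0 : min(t1, n - 1) + 1]
    if tail.size < 2:
        raise DegenerateSweepError(
            f"tail window [{t0}, {t1}] needs >= 2 samples, sweep has {n}"
        )
    thr = cfg.artifact_sd_factor * float(np.std(tail, ddof=1))
    exceeds = np.abs(delta) > thr
    any_c1 = bool(exceeds.any())
    if not any_c1:
        return np.empty(0, dtype=int), False

    fs_scale = protocol.sampling_rate_hz / 1000.0
    p = int(round(protocol.inter_pulse_interval_ms * fs_scale))
    lo, hi = cfg.artifact_search_samples
    lo = max(lo, 1)  # C4 needs a previous sample
    hi = min(hi, n - 2 * p - 1, n - 2)  # C3 needs t + 2p, C4 needs t + 1
    if hi < lo:
        return np.empty(0, dtype=int), any_c1

    t = np.arange(lo, hi + 1)
    c1 = exceeds[t]
    c2 = exceeds[t + p]
    c3 = ~exceeds[t + 2 * p]
    mf = raw - np.median(raw)
    s = np.sign(mf)
    c4 = (s[t] != s[t - 1]) | (s[t] != s[t + 1])
    return t[c1 & c2 & c3 & c4], any_c1


def detect_first_artifact(
    sweep: SweepRecord, protocol: ProtocolConfig, cfg: AnalysisConfig
) -> DetectionResult:
    """Locate the first stimulation artifact on the quadriceps channels.

    The earliest candidate across LQ and RQ wins (tie: LQ, by channel
    order).  ``baseline`` is returned when C1 holds for no sample on any
    detection channel; ``discarded`` when C1 fires but no sample meets
    C1-C4 within the search interval.
    """
    channels = [m for m in DETECTION_CHANNELS if m in sweep.samples]
    if not channels:
        raise DegenerateSweepError(
            f"sweep {sweep.key} lacks the quadriceps detection channels"
        )
    per_channel: dict[str, Optional[int]] = {}
    any_c1 = False
    best: tuple[int, str] | None = None
    for ch in channels:
        cands, ch_c1 = _channel_candidates(sweep.samples[ch], protocol, cfg)
        any_c1 = any_c1 or ch_c1
        per_channel[ch] = int(cands[0]) if cands.size else None
        if cands.size and (best is None or cands[0] < best[0]):
            best = (int(cands[0]), ch)
    if best is not None:
        return DetectionResult(ALIGNED, best[0], best[1], per_channel)
    if not any_c1:
        return DetectionResult(BASELINE, None, None, per_channel)
    return DetectionResult(DISCARDED, None, None, per_channel)


def _crop_bounds(protocol: ProtocolConfig, cfg: AnalysisConfig) -> tuple[int, int]:
    pre = -protocol.ms_to_samples(cfg.crop_window_ms[0])
    post = protocol.ms_to_samples(cfg.crop_window_ms[1])
    return pre, post


def align_sweep(
    sweep: SweepRecord,
    onset: int,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> AlignedSweep:
    """Crop all channels to the [-30, 300] ms window around *onset*.

    The aligned sweep has 331 samples at 1 kHz with t = 0 at index 30.  If
    the window does not fit inside the recording the sweep is discarded
    (no padding: downstream windows up to 300 ms must hold real data).
    """
    pre, post = _crop_bounds(protocol, cfg)
    n = sweep.n_samples()
    if onset - pre < 0 or onset + post > n - 1:
        return AlignedSweep(sweep, DISCARDED, None, None, 0, protocol.sampling_rate_hz)
    samples = {
        m: np.array(x[onset - pre : onset + post + 1], dtype=float)
        for m, x in sweep.samples.items()
    }
    return AlignedSweep(sweep, ALIGNED, int(onset), samples, pre, protocol.sampling_rate_hz)


def extract_baseline(
    sweep: SweepRecord, protocol: ProtocolConfig, cfg: AnalysisConfig = AnalysisConfig()
) -> AlignedSweep:
    """Keep the first crop-length samples of an artifact-free sweep.

    The nominal time axis matches aligned sweeps so that noise and
    similarity windows apply uniformly.
    """
    pre, post = _crop_bounds(protocol, cfg)
    length = pre + post + 1
    if sweep.n_samples() < length:
        return AlignedSweep(sweep, DISCARDED, None, None, 0, protocol.sampling_rate_hz)
    samples = {m: np.array(x[:length], dtype=float) for m, x in sweep.samples.items()}
    return AlignedSweep(sweep, BASELINE, None, samples, pre, protocol.sampling_rate_hz)


def synchronize(
    sweep: SweepRecord, protocol: ProtocolConfig, cfg: AnalysisConfig = AnalysisConfig()
) -> AlignedSweep:
    """Detect, then align / extract baseline / discard one sweep."""
    det = detect_first_artifact(sweep, protocol, cfg)
    if det.status == ALIGNED:
        assert det.onset_index is not None
        return align_sweep(sweep, det.onset_index, protocol, cfg)
    if det.status == BASELINE:
        return extract_baseline(sweep, protocol, cfg)
    return AlignedSweep(sweep, DISCARDED, None, None, 0, protocol.sampling_rate_hz)


def synchronize_session(
    records, protocol: ProtocolConfig, cfg: AnalysisConfig = AnalysisConfig()
) -> list[AlignedSweep]:
    return [synchronize(r, protocol, cfg) for r in records]
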