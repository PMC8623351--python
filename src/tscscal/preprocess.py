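"""Filtering, noise profiling, repetition similarity gating and averaging.

Each aligned sweep is offset-corrected (median removal), the stimulation
artifacts are blanked (set to 0) in the closed intervals [-2, 2] ms and
[48, 52] ms around the two pulses, and the signal is passed through a
2nd-order Butterworth band-stop (43-47 Hz) and a 1st-order Butterworth
low-pass (300 Hz).  Both filters are applied non-causally
(forward-backward), so the cascade has zero net phase and response
latencies in the 10-45 ms feature windows are preserved.  The blanked
intervals are restored (re-zeroed) after filtering.

The muscle-specific base noise level is the SD of all filtered samples
with 100 <= t <= 300 ms pooled over every retained sweep of the session —
a window late enough to contain no evoked activity.

The three repetitions recorded per (electrode, amplitude) are compared
pairwise by the RMSE over 5-45 ms plus 55-95 ms; a pair is similar when
its RMSE is below 16x the muscle's base noise level.  The largest mutually
similar subset (>= 2 sweeps) is averaged on the -1..200 ms window; if no
such subset exists the (muscle, electrode, amplitude) cell is invalid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig, ConfigurationError, ProtocolConfig
from .sync import ALIGNED, BASELINE, AlignedSweep


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseProfile:
    """Per-muscle base noise level (SD of late-window EMG, in uV)."""

    level_uV: Mapping[str, float]
    n_samples: Mapping[str, int] = field(default_factory=dict)

    def __getitem__(self, muscle: str) -> float:
        return self.level_uV[muscle]


@dataclass(frozen=True)
class GateResult:
    """Outcome of the similarity gate for one (muscle, electrode, amplitude)."""

    kept: tuple[int, ...]  # repetition numbers retained
    valid: bool
    reason: Optional[str] = None
    rmse: Optional[Mapping[tuple[int, int], float]] = None


@dataclass(frozen=True)
class AveragedResponse:
    """Mean filtered EMG per muscle for one (electrode, amplitude) cell,
    on the -1..200 ms window (202 samples at 1 kHz)."""

    electrode_position: int
    amplitude_mA: float
    series: Mapping[str, Optional[np.ndarray]] = field(repr=False)
    n_averaged: Mapping[str, int]
    valid: Mapping[str, bool]
    reasons: Mapping[str, Optional[str]]
    t_start_ms: float
    sampling_rate_hz: float

    def window_slice(self, t_lo_ms: float, t_hi_ms: float) -> slice:
        fs = self.sampling_rate_hz
        off = -self.t_start_ms
        lo = int(round((t_lo_ms + off) * fs / 1000.0))
        hi = int(round((t_hi_ms + off) * fs / 1000.0))
        series_len = next((len(s) for s in self.series.values() if s is not None), 0)
        if lo < 0 or hi >= series_len:
            raise PreprocessError(f"window [{t_lo_ms}, {t_hi_ms}] ms outside averaged series")
        return slice(lo, hi + 1)


# -- filtering ---------------------------------------------------------------


@lru_cache(maxsize=8)
def _design_cascade(
    fs: float, bandstop: tuple[float, float], bs_order: int, lowpass: float, lp_order: int
) -> np.ndarray:
    if fs <= 2.0 * lowpass:
        raise ConfigurationError(
            f"sampling rate {fs} Hz cannot support a {lowpass} Hz low-pass"
        )
    sos_bs = sps.butter(bs_order, bandstop, btype="bandstop", fs=fs, output="sos")
    sos_lp = sps.butter(lp_order, lowpass, btype="lowpass", fs=fs, output="sos")
    return np.vstack([sos_bs, sos_lp])


def zero_phase_filter(x: np.ndarray, fs: float, cfg: AnalysisConfig) -> np.ndarray:
    """Band-stop + low-pass cascade, applied forward-backward (zero phase)."""
    sos = _design_cascade(
        float(fs), tuple(cfg.bandstop_hz), cfg.bandstop_order, cfg.lowpass_hz, cfg.lowpass_order
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def prefilter(
    sweep: AlignedSweep, protocol: ProtocolConfig, cfg: AnalysisConfig = AnalysisConfig()
) -> AlignedSweep:
    """Median removal, artifact blanking, zero-phase filtering, re-blanking.

    Baseline sweeps contain no artifact, so blanking is skipped for them;
    discarded sweeps are rejected.
    """
    if sweep.status not in (ALIGNED, BASELINE):
        raise PreprocessError("cannot prefilter a discarded sweep")
    blank = sweep.status == ALIGNED
    slices = [sweep.window_slice(lo, hi) for lo, hi in cfg.blank_windows_ms] if blank else []
    out: dict[str, np.ndarray] = {}
    for muscle, x in sweep.samples.items():
        y = x - np.median(x)
        for sl in slices:
            y[sl] = 0.0
        y = zero_phase_filter(y, sweep.sampling_rate_hz, cfg)
        for sl in slices:
            y[sl] = 0.0
        out[muscle] = y
    return sweep.replace_samples(out)


# -- noise profile -----------------------------------------------------------


def noise_profile(
    sweeps: Sequence[AlignedSweep],
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> NoiseProfile:
    """Pool the 100-300 ms window of every retained filtered sweep per muscle
    and take the sample SD."""
    pooled: dict[str, list[np.ndarray]] = {m: [] for m in protocol.muscle_labels}
    for sw in sweeps:
        if sw.status not in (ALIGNED, BASELINE):
            continue
        sl = sw.window_slice(*cfg.noise_window_ms)
        for muscle, x in sw.samples.items():
            if muscle in pooled:
                pooled[muscle].append(x[sl])
    levels: dict[str, float] = {}
    counts: dict[str, int] = {}
    for muscle, chunks in pooled.items():
        if not chunks:
            raise PreprocessError(f"no usable sweeps to profile noise for muscle {muscle}")
        allx = np.concatenate(chunks)
        levels[muscle] = float(np.std(allx, ddof=1)) if allx.size > 1 else 0.0
        counts[muscle] = int(allx.size)
    return NoiseProfile(levels, counts)


# -- similarity gate ---------------------------------------------------------


def _similarity_segment(sweep: AlignedSweep, muscle: str, cfg: AnalysisConfig) -> np.ndarray:
    parts = [sweep.samples[muscle][sweep.window_slice(lo, hi)] for lo, hi in cfg.similarity_windows_ms]
    return np.concatenate(parts)


def similarity_gate(
    repetitions: Sequence[AlignedSweep],
    muscle: str,
    noise: NoiseProfile,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> GateResult:
    """Select the largest mutually similar subset of repetitions.

    Pairwise RMSE over the concatenated 5-45 and 55-95 ms windows; a pair
    is similar iff RMSE < similarity_factor * base noise level of *muscle*.
    Subsets of equal size are tie-broken toward the lowest repetition
    numbers.  Fewer than two usable repetitions, or no similar pair, makes
    the cell invalid.
    """
    reps = sorted(repetitions, key=lambda s: s.repetition)
    if len(reps) < 2:
        return GateResult((), False, "insufficient repetitions")
    threshold = cfg.similarity_factor * noise[muscle]
    segs = {s.repetition: _similarity_segment(s, muscle, cfg) for s in reps}
    ids = [s.repetition for s in reps]
    rmse: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(ids, 2):
        rmse[(a, b)] = float(np.sqrt(np.mean((segs[a] - segs[b]) ** 2)))

    def mutually_similar(subset: tuple[int, ...]) -> bool:
        return all(rmse[(a, b)] < threshold for a, b in itertools.combinations(subset, 2))

    for size in range(len(ids), 1, -1):
        for subset in itertools.combinations(ids, size):  # lexicographic = lowest ids first
            if mutually_similar(subset):
                return GateResult(subset, True, None, rmse)
    return GateResult((), False, "no similar repetitions", rmse)


# -- averaging ---------------------------------------------------------------


def average(
    subset: Sequence[AlignedSweep],
    muscle: str,
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> np.ndarray:
    """Pointwise mean of similar repetitions cropped to -1..200 ms."""
    if len(subset) < 2:
        raise PreprocessError("averaging requires at least two similar repetitions")
    lengths = {s.n_samples() for s in subset}
    if len(lengths) != 1:
        raise PreprocessError(f"mismatched sweep lengths in average: {sorted(lengths)}")
    sl = subset[0].window_slice(*cfg.average_window_ms)
    stack = np.stack([s.samples[muscle][sl] for s in subset])
    return stack.mean(axis=0)


def preprocess_session(
    aligned: Sequence[AlignedSweep],
    protocol: ProtocolConfig,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[AveragedResponse], NoiseProfile, list[AlignedSweep]]:
    """Filter all retained sweeps, profile noise, gate and average each
    (electrode, amplitude) cell.

    Cells with >= 2 aligned repetitions are gated on those; cells whose only
    usable repetitions are baseline sweeps (no stimulation artifact, e.g.
    low amplitudes at rostral positions) are gated and averaged on the
    baseline sweeps' nominal time axis — such cells evaluate as
    no-response downstream.  Returns (averaged responses, noise profile,
    filtered sweeps).
    """
    filtered = [
        prefilter(sw, protocol, cfg) if sw.status in (ALIGNED, BASELINE) else sw
        for sw in aligned
    ]
    usable = [sw for sw in filtered if sw.status in (ALIGNED, BASELINE)]
    if not usable:
        raise PreprocessError("no usable sweeps in session (all discarded)")
    noise = noise_profile(usable, protocol, cfg)

    cells: dict[tuple[int, float], list[AlignedSweep]] = {}
    for sw in filtered:
        cells.setdefault((sw.electrode_position, sw.amplitude_mA), []).append(sw)

    responses: list[AveragedResponse] = []
    for (n, amp), sweeps in sorted(cells.items()):
        al = [s for s in sweeps if s.status == ALIGNED]
        bl = [s for s in sweeps if s.status == BASELINE]
        pool = al if len(al) >= 2 else (bl if len(bl) >= 2 else [])
        series: dict[str, Optional[np.ndarray]] = {}
        n_avg: dict[str, int] = {}
        valid: dict[str, bool] = {}
        reasons: dict[str, Optional[str]] = {}
        for muscle in protocol.muscle_labels:
            if not pool:
                series[muscle] = None
                n_avg[muscle] = 0
                valid[muscle] = False
                reasons[muscle] = "insufficient repetitions"
                continue
            gate = similarity_gate(pool, muscle, noise, cfg)
            if not gate.valid:
                series[muscle] = None
                n_avg[muscle] = 0
                valid[muscle] = False
                reasons[muscle] = gate.reason
                continue
            kept = [s for s in pool if s.repetition in gate.kept]
            series[muscle] = average(kept, muscle, protocol, cfg)
            n_avg[muscle] = len(kept)
            valid[muscle] = True
            reasons[muscle] = None
        responses.append(
            AveragedResponse(
                electrode_position=n,
                amplitude_mA=amp,
                series=series,
                n_averaged=n_avg,
                valid=valid,
                reasons=reasons,
                t_start_ms=cfg.average_window_ms[0],
                sampling_rate_hz=protocol.sampling_rate_hz,
            )
        )
    return responses, noise, filtered
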