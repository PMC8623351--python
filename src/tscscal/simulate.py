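"""Synthetic calibration sessions with known ground truth.

The generator emulates the signal features the pipeline must cope with:

* biphasic stimulation artifacts at the two pulse times (50 ms apart),
  with the sweep onset jittered so synchronization is genuinely exercised;
* evoked responses as short biphasic wavelets whose amplitude follows a
  sigmoid recruitment curve over stimulation amplitude, with
  electrode-position-dependent thresholds;
* strong paired-pulse suppression for reflex responses and essentially
  none for M-waves;
* Gaussian white baseline noise, optionally with a 45 Hz interference
  line (exercising the band-stop filter);
* occasional movement-corrupted repetitions (large slow oscillation) that
  must be rejected by the similarity gate.

Every drawn quantity derives from the seed stored in the ground truth, so
the same truth reproduces bit-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np

from .config import AnalysisConfig, ConfigurationError, ProtocolConfig
from .evaluate import (
    RatingCell,
    RatingLabel,
    RatingMatrix,
    ResponseFeatures,
    classify,
    suppression,
)
from .session import SweepRecord

RESPONSE_TYPES = ("reflex", "m_wave", "none")


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth response of one muscle to one electrode position."""

    response_type: str  # reflex | m_wave | none
    threshold_mA: float = 40.0  # sigmoid midpoint of the recruitment curve
    suppression: float = 0.85  # paired-pulse suppression of the response
    latency_ms: float = 15.0  # response onset after the stimulus
    max_amp_uV: float = 600.0  # saturation peak-to-peak amplitude

    def __post_init__(self) -> None:
        if self.response_type not in RESPONSE_TYPES:
            raise ConfigurationError(f"unknown response type {self.response_type!r}")
        if not (0.0 <= self.suppression <= 1.0):
            raise ConfigurationError("suppression must be in [0, 1]")


@dataclass(frozen=True)
class SimGroundTruth:
    """Complete ground truth of a simulated session."""

    sites: Mapping[tuple[str, int], SiteTruth]
    noise_sd_uV: float = 5.0
    artifact_amp_uV: float = 500.0
    mains_45hz_uV: float = 0.0
    corrupted_rate: float = 0.05  # per-cell probability of one bad repetition
    corruption_amp_uV: float = 1000.0  # gross movement artifact is mV-scale
    recruitment_slope_mA: float = 1.0
    seed: int = 0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = [
            {"muscle": m, "electrode_position": n, **asdict(site)}
            for (m, n), site in sorted(self.sites.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimGroundTruth":
        d = dict(d)
        sites = {}
        for row in d.pop("sites"):
            row = dict(row)
            key = (row.pop("muscle"), int(row.pop("electrode_position")))
            sites[key] = SiteTruth(**row)
        return cls(sites=sites, **d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimGroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def response_waveform(latency_ms: float, amplitude_uV: float, t_ms: np.ndarray) -> np.ndarray:
    """Biphasic response wavelet: Gaussian-windowed single-cycle sine,
    ~8 ms wide, onset at *latency_ms*, peak-to-peak scaled to
    *amplitude_uV* on the given time grid."""
    if not (10.0 <= latency_ms <= 40.0):
        raise ConfigurationError(
            f"latency {latency_ms} ms outside [10, 40] (peaks must fall in the "
            "10-45 ms evaluation window)"
        )
    t = np.asarray(t_ms, dtype=float)
    if amplitude_uV == 0:
        return np.zeros_like(t)
    width = 8.0
    center = latency_ms + width / 2.0
    shape = np.sin(2.0 * np.pi * (t - latency_ms) / width) * np.exp(
        -0.5 * ((t - center) / (width / 4.0)) ** 2
    )
    ptp = float(np.max(shape) - np.min(shape))
    if ptp == 0:
        return np.zeros_like(t)
    return shape * (amplitude_uV / ptp)


def recruitment(
    amplitude_mA: float, threshold_mA: float, max_amp_uV: float, slope_mA: float = 1.0
) -> float:
    """Sigmoid recruitment curve: ~0 well below the threshold, half of
    *max_amp_uV* at the threshold (midpoint), saturating above it."""
    if threshold_mA <= 0 or max_amp_uV < 0 or slope_mA <= 0:
        raise ConfigurationError("recruitment parameters must be positive")
    z = (amplitude_mA - threshold_mA) / slope_mA
    return float(max_amp_uV / (1.0 + np.exp(-np.clip(z, -500, 500))))


def generate_session(
    truth: SimGroundTruth, protocol: ProtocolConfig = ProtocolConfig()
) -> list[SweepRecord]:
    """Simulate the full amplitude-ramp protocol described by *truth*.

    Each sweep is baseline noise plus two biphasic artifact spikes (at a
    jittered onset and one inter-pulse interval later) plus the evoked
    responses of every muscle, the second response scaled by
    ``1 - suppression``.  Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    fs = protocol.sampling_rate_hz
    n_samp = protocol.sweep_samples
    p = protocol.inter_pulse_samples
    records: list[SweepRecord] = []
    for n in protocol.electrode_positions:
        for I in protocol.amplitude_grid_mA:
            corrupt_j = -1
            if rng.random() < truth.corrupted_rate:
                corrupt_j = int(rng.integers(1, protocol.repetitions_per_amplitude + 1))
            for j in range(1, protocol.repetitions_per_amplitude + 1):
                onset = int(rng.integers(30, 81))  # keeps t* inside the search window
                t_ms = (np.arange(n_samp) - onset) * 1000.0 / fs
                channels: dict[str, np.ndarray] = {}
                for muscle in protocol.muscle_labels:
                    x = truth.noise_sd_uV * rng.standard_normal(n_samp)
                    if truth.mains_45hz_uV > 0:
                        phase = rng.uniform(0, 2 * np.pi)
                        x += truth.mains_45hz_uV * np.sin(
                            2 * np.pi * 45.0 * np.arange(n_samp) / fs + phase
                        )
                    if truth.artifact_amp_uV > 0:
                        for k in (onset, onset + p):
                            if k + 1 < n_samp:
                                x[k] += truth.artifact_amp_uV
                                x[k + 1] -= truth.artifact_amp_uV
                    site = truth.sites.get((muscle, n))
                    if site is not None and site.response_type != "none":
                        a1 = recruitment(
                            I, site.threshold_mA, site.max_amp_uV, truth.recruitment_slope_mA
                        )
                        a2 = a1 * (1.0 - site.suppression)
                        x += response_waveform(site.latency_ms, a1, t_ms)
                        x += response_waveform(
                            site.latency_ms, a2, t_ms - protocol.inter_pulse_interval_ms
                        )
                    if j == corrupt_j:
                        # movement transient triggered around the stimuli: an
                        # 8 Hz burst confined to the response epoch, so the
                        # late (>=100 ms) rest window stays clean
                        phase = rng.uniform(0, 2 * np.pi)
                        burst = truth.corruption_amp_uV * np.sin(
                            2 * np.pi * 8.0 * np.arange(n_samp) / fs + phase
                        )
                        lo = max(onset - int(0.02 * fs), 0)
                        hi = min(onset + int(0.095 * fs), n_samp)
                        env = np.zeros(n_samp)
                        env[lo:hi] = np.hanning(hi - lo)
                        x += burst * env
                    channels[muscle] = x
                records.append(SweepRecord(n, float(I), j, channels))
    return records


def default_ground_truth(
    seed: int,
    protocol: ProtocolConfig = ProtocolConfig(),
    best_electrode: Optional[int] = None,
    best_threshold_mA: Optional[float] = None,
    quiet: bool = False,
    **overrides,
) -> SimGroundTruth:
    """Construct a realistic high-SNR session truth.

    One electrode position (the ground-truth best) recruits reflex
    responses in all four muscles at low thresholds; its neighbors recruit
    only a quadriceps reflex pair (plus one presumed M-wave) at clearly
    higher thresholds; remote positions stay silent.  ``quiet=True``
    produces a no-response session (artifacts present, no evoked activity),
    as seen in participants without elicitable reflexes.

    *best_threshold_mA* pins the best electrode's amplitude threshold I'
    (its lowest reflex threshold) to an exact grid value.
    """
    rng = np.random.default_rng(seed)
    positions = protocol.electrode_positions
    grid = protocol.amplitude_grid_mA
    step = protocol.amplitude_step_mA
    sites: dict[tuple[str, int], SiteTruth] = {}

    if quiet:
        for n in positions:
            for m in protocol.muscle_labels:
                sites[(m, n)] = SiteTruth("none")
        return SimGroundTruth(sites=sites, seed=seed, **overrides)

    if best_electrode is None:
        best_electrode = int(rng.choice(positions))
    if best_electrode not in positions:
        raise ConfigurationError(f"best electrode {best_electrode} not in protocol")

    # thresholds are drawn on the grid so that label flips happen exactly at
    # grid points and I' recovery can be checked at grid resolution
    lo_choices = [a for a in grid if 6 * step <= a <= 9 * step] or list(grid)
    hi_choices = [a for a in grid if 11 * step <= a <= 13 * step] or [grid[-1]]

    def draw(choices) -> float:
        return float(rng.choice(choices))

    best_thresholds = sorted(draw(lo_choices) for _ in protocol.muscle_labels)
    if best_threshold_mA is not None:
        if best_threshold_mA not in grid:
            raise ConfigurationError("best_threshold_mA must lie on the amplitude grid")
        shift = best_threshold_mA - best_thresholds[0]
        best_thresholds = [
            min(t + shift, grid[-1] - step) for t in best_thresholds
        ]
        best_thresholds[0] = best_threshold_mA

    for m, thr in zip(protocol.muscle_labels, best_thresholds):
        sites[(m, best_electrode)] = SiteTruth(
            "reflex",
            threshold_mA=thr,
            suppression=0.85,
            latency_ms=float(rng.uniform(12, 25)),
        )
    for n in positions:
        if n == best_electrode:
            continue
        if abs(n - best_electrode) == 1:
            # neighbor: weaker site — quadriceps reflex pair + one M-wave
            kinds = {"LQ": "reflex", "RQ": "reflex", "LTS": "m_wave", "RTS": "none"}
            for m in protocol.muscle_labels:
                kind = kinds.get(m, "none")
                if kind == "none":
                    sites[(m, n)] = SiteTruth("none")
                else:
                    sites[(m, n)] = SiteTruth(
                        kind,
                        threshold_mA=draw(hi_choices),
                        suppression=0.85 if kind == "reflex" else 0.05,
                        latency_ms=float(rng.uniform(12, 25)),
                    )
        else:
            for m in protocol.muscle_labels:
                sites[(m, n)] = SiteTruth("none")
    return SimGroundTruth(sites=sites, seed=seed, **overrides)


# -- analytic expectations ---------------------------------------------------


def expected_rating_matrix(
    truth: SimGroundTruth,
    protocol: ProtocolConfig = ProtocolConfig(),
    cfg: AnalysisConfig = AnalysisConfig(),
) -> RatingMatrix:
    """Noise-free rating matrix implied by the ground truth.

    Features are taken from the recruitment curve and the true suppression
    levels (no noise, no invalid cells); labels follow the standard
    classification gates with the true noise SD."""
    cells: dict[tuple[str, int, float], RatingCell] = {}
    for n in protocol.electrode_positions:
        for I in protocol.amplitude_grid_mA:
            for m in protocol.muscle_labels:
                site = truth.sites.get((m, n))
                if site is None or site.response_type == "none":
                    feats = ResponseFeatures(0.0, 0.0, 0.0, suppression_defined=False)
                else:
                    a1 = recruitment(
                        I, site.threshold_mA, site.max_amp_uV, truth.recruitment_slope_mA
                    )
                    a2 = a1 * (1.0 - site.suppression)
                    feats = ResponseFeatures(a1, a2, suppression(a1, a2), a1 > 0)
                cells[(m, n, I)] = RatingCell(classify(feats, truth.noise_sd_uV, cfg), feats)
    return RatingMatrix(cells, tuple(protocol.muscle_labels))
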