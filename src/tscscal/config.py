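"""Configuration objects for the calibration pipeline.

Two configuration layers are kept apart:

* :class:`ProtocolConfig` describes the stimulation protocol that produced a
  session — electrode positions, the amplitude ramp, repetitions, the
  inter-pulse interval of the paired stimuli, the EMG sampling rate and the
  muscle montage.  It is what the recording hardware was told to do.
* :class:`AnalysisConfig` collects every tunable of the signal-processing and
  decision chain — detection thresholds, filter corners, blanking and feature
  windows, the similarity factor, classification gates and the therapy rule.

All time windows are expressed in milliseconds and converted to sample
indices at the point of use, so non-default sampling rates are supported.
Amplitudes are microvolts (EMG) and milliamperes (stimulation) throughout;
no auto-scaling is performed because the 50 uV response gate is absolute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration violates an invariant."""


def _default_grid() -> tuple[float, ...]:
    return tuple(float(a) for a in range(5, 80, 5))


def _default_grouping() -> dict[str, str]:
    return {"LQ": "left", "LTS": "left", "RQ": "right", "RTS": "right"}


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation-protocol description for one calibration session.

    Defaults reproduce the standard protocol: four paraspinal electrode
    positions tested caudal to rostral, three double stimuli (50 ms
    inter-pulse interval) per amplitude, amplitudes ramped 5..75 mA in 5 mA
    steps, EMG from left/right quadriceps (LQ/RQ) and triceps surae
    (LTS/RTS) sampled at 1 kHz in 600 ms sweeps.
    """

    electrode_positions: tuple[int, ...] = (1, 2, 3, 4)
    amplitude_grid_mA: tuple[float, ...] = field(default_factory=_default_grid)
    repetitions_per_amplitude: int = 3
    inter_pulse_interval_ms: float = 50.0
    sampling_rate_hz: float = 1000.0
    muscle_labels: tuple[str, ...] = ("LQ", "LTS", "RQ", "RTS")
    limb_grouping: Mapping[str, str] = field(default_factory=_default_grouping)
    sweep_duration_ms: float = 600.0

    def __post_init__(self) -> None:
        grid = tuple(float(a) for a in self.amplitude_grid_mA)
        object.__setattr__(self, "amplitude_grid_mA", grid)
        object.__setattr__(self, "electrode_positions", tuple(int(n) for n in self.electrode_positions))
        object.__setattr__(self, "muscle_labels", tuple(self.muscle_labels))
        if len(grid) < 1:
            raise ConfigurationError("amplitude grid is empty")
        steps = [b - a for a, b in zip(grid, grid[1:])]
        if any(s <= 0 for s in steps):
            raise ConfigurationError("amplitude grid must be strictly increasing")
        if steps and any(abs(s - steps[0]) > 1e-9 for s in steps):
            raise ConfigurationError("amplitude grid must have a constant step")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling rate must be positive")
        ipi_samples = self.inter_pulse_interval_ms * self.sampling_rate_hz / 1000.0
        if abs(ipi_samples - round(ipi_samples)) > 1e-9:
            raise ConfigurationError(
                "inter-pulse interval must be a whole number of samples "
                f"(got {ipi_samples} samples)"
            )
        missing = [m for m in self.muscle_labels if m not in self.limb_grouping]
        if missing:
            raise ConfigurationError(f"muscles without sensor group: {missing}")
        if self.repetitions_per_amplitude < 1:
            raise ConfigurationError("repetitions_per_amplitude must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def amplitude_step_mA(self) -> float:
        if len(self.amplitude_grid_mA) == 1:
            return self.amplitude_grid_mA[0]
        return self.amplitude_grid_mA[1] - self.amplitude_grid_mA[0]

    @property
    def inter_pulse_samples(self) -> int:
        return int(round(self.inter_pulse_interval_ms * self.sampling_rate_hz / 1000.0))

    @property
    def sweep_samples(self) -> int:
        return int(round(self.sweep_duration_ms * self.sampling_rate_hz / 1000.0))

    def ms_to_samples(self, t_ms: float) -> int:
        """Convert a time offset in ms to the nearest whole sample."""
        return int(round(t_ms * self.sampling_rate_hz / 1000.0))

    def sensor_groups(self) -> dict[str, tuple[str, ...]]:
        groups: dict[str, list[str]] = {}
        for m in self.muscle_labels:
            groups.setdefault(self.limb_grouping[m], []).append(m)
        return {g: tuple(ms) for g, ms in groups.items()}

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["limb_grouping"] = dict(self.limb_grouping)
        d["electrode_positions"] = list(self.electrode_positions)
        d["amplitude_grid_mA"] = list(self.amplitude_grid_mA)
        d["muscle_labels"] = list(self.muscle_labels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown protocol config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "ProtocolConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the processing and decision chain.

    Windows that are anchored to the first stimulus (t = 0 after
    synchronization) are given in ms.  ``artifact_search_samples`` and
    ``tail_window_samples`` refer to 0-based raw-sweep indices (the
    conventional 1-based sample ranges [10, 200] and [300, 600] map to
    [9, 199] and [299, 599]).
    """

    # synchronizer
    artifact_search_samples: tuple[int, int] = (9, 199)
    tail_window_samples: tuple[int, int] = (299, 599)
    artifact_sd_factor: float = 3.0
    crop_window_ms: tuple[float, float] = (-30.0, 300.0)

    # preprocessor
    blank_windows_ms: tuple[tuple[float, float], ...] = ((-2.0, 2.0), (48.0, 52.0))
    bandstop_hz: tuple[float, float] = (43.0, 47.0)
    bandstop_order: int = 2
    lowpass_hz: float = 300.0
    lowpass_order: int = 1
    noise_window_ms: tuple[float, float] = (100.0, 300.0)
    similarity_windows_ms: tuple[tuple[float, float], ...] = ((5.0, 45.0), (55.0, 95.0))
    similarity_factor: float = 16.0
    average_window_ms: tuple[float, float] = (-1.0, 200.0)

    # evaluator
    amp_window_ms: tuple[float, float] = (10.0, 45.0)
    min_amp_uV: float = 50.0
    noise_sd_factor: float = 6.0
    suppression_threshold: float = 0.60

    # recommender
    therapy_fraction: float = 0.9
    rounding: str = "grid"
    min_green_muscles: int = 2

    def __post_init__(self) -> None:
        if self.rounding not in ("grid", "none"):
            raise ConfigurationError("rounding must be 'grid' or 'none'")
        if not (0 < self.therapy_fraction < 1):
            raise ConfigurationError("therapy_fraction must be in (0, 1)")
        if self.similarity_factor <= 0:
            raise ConfigurationError("similarity_factor must be positive")
        lo, hi = self.amp_window_ms
        if lo >= hi:
            raise ConfigurationError("amp window must be increasing")
        # the feature windows must not touch the blanked artifact intervals,
        # otherwise peak-to-peak would silently measure restored zeros
        for which in (0.0, 50.0):
            w = (lo + which, hi + which)
            for b in self.blank_windows_ms:
                if w[0] <= b[1] and b[0] <= w[1]:
                    raise ConfigurationError(
                        f"amplitude window {w} overlaps blanking window {b}"
                    )
        for w in self.similarity_windows_ms + (self.noise_window_ms, self.average_window_ms):
            if w[0] >= w[1]:
                raise ConfigurationError(f"window {w} must be increasing")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("blank_windows_ms", "similarity_windows_ms"):
            if key in kw:
                kw[key] = tuple(tuple(w) for w in kw[key])
        for key in (
            "artifact_search_samples",
            "tail_window_samples",
            "crop_window_ms",
            "bandstop_hz",
            "noise_window_ms",
            "average_window_ms",
            "amp_window_ms",
        ):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_session_config(path) -> tuple[ProtocolConfig, AnalysisConfig]:
    """Load a combined session config JSON.

    The file may contain the :class:`ProtocolConfig` fields at top level
    (the session-config dialect) or split into ``protocol`` / ``analysis``
    sections.  Missing sections fall back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    if "protocol" in d or "analysis" in d:
        proto = ProtocolConfig.from_dict(d.get("protocol", {}))
        ana = AnalysisConfig.from_dict(d.get("analysis", {}))
        return proto, ana
    return ProtocolConfig.from_dict(d), AnalysisConfig()
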