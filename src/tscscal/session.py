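"""Session data model and long-format CSV I/O.

A calibration *session* is the complete set of raw EMG sweeps recorded while
the automated protocol steps through electrode positions ``n``, stimulation
amplitudes ``I`` and repetitions ``j``.  On disk a session is a long-format
CSV with mandatory header::

    electrode_position,amplitude_mA,repetition,muscle,sample_index,value_uV

``sample_index`` is 0-based and contiguous per channel; values are raw EMG
in microvolts.  Missing ``(n, I, j)`` combinations are permitted (the
protocol may stop early at the tolerance limit) and reported via
:class:`SessionGapWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ProtocolConfig

SESSION_COLUMNS = (
    "electrode_position",
    "amplitude_mA",
    "repetition",
    "muscle",
    "sample_index",
    "value_uV",
)


class SessionFormatError(ValueError):
    """Malformed session file (bad header, non-numeric value, bad shape)."""


class SessionIntegrityError(ValueError):
    """Duplicate or internally inconsistent session rows."""


class SessionGapWarning(UserWarning):
    """Emitted when (electrode, amplitude, repetition) cells are missing."""


@dataclass(frozen=True)
class SweepRecord:
    """One raw paired-pulse EMG recording: all muscle channels of one
    (electrode position, amplitude, repetition)."""

    electrode_position: int
    amplitude_mA: float
    repetition: int
    samples: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        clean = {}
        for muscle, x in self.samples.items():
            arr = np.asarray(x, dtype=float)
            if arr.ndim != 1:
                raise SessionFormatError(f"channel {muscle} is not 1-D")
            if not np.all(np.isfinite(arr)):
                raise SessionFormatError(f"channel {muscle} contains non-finite samples")
            clean[muscle] = arr
        object.__setattr__(self, "samples", clean)

    @property
    def key(self) -> tuple[int, float, int]:
        return (self.electrode_position, self.amplitude_mA, self.repetition)

    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    def validate_groups(self, config: ProtocolConfig) -> None:
        """Channels acquired by one sensor must share a common length."""
        for group, muscles in config.sensor_groups().items():
            lens = {len(self.samples[m]) for m in muscles if m in self.samples}
            if len(lens) > 1:
                raise SessionIntegrityError(
                    f"sweep {self.key}: unequal channel lengths in sensor group "
                    f"'{group}': {sorted(lens)}"
                )


def read_session(path, config: ProtocolConfig) -> list[SweepRecord]:
    """Read a long-format session CSV into :class:`SweepRecord` objects.

    Raises :class:`SessionFormatError` naming the offending line for
    non-numeric values, :class:`SessionIntegrityError` for duplicate
    ``(n, I, j, muscle, sample_index)`` rows, and warns with
    :class:`SessionGapWarning` when combinations expected from *config*
    are absent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SessionFormatError(f"missing columns {missing_cols} in {path}")
    converted = {}
    for col in ("electrode_position", "amplitude_mA", "repetition", "sample_index", "value_uV"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.index[num.isna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise SessionFormatError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"'{col}' at line {int(bad[0]) + 2} of {path}"
            )
        converted[col] = num
    df = pd.DataFrame({**converted, "muscle": df["muscle"]})

    dup = df.duplicated(
        subset=["electrode_position", "amplitude_mA", "repetition", "muscle", "sample_index"]
    )
    if dup.any():
        row = df[dup].iloc[0]
        raise SessionIntegrityError(
            "duplicate sample: n=%d I=%g j=%d muscle=%s sample=%d"
            % (
                row.electrode_position,
                row.amplitude_mA,
                row.repetition,
                row.muscle,
                row.sample_index,
            )
        )

    records: list[SweepRecord] = []
    grouped = df.sort_values("sample_index").groupby(
        ["electrode_position", "amplitude_mA", "repetition"], sort=True
    )
    for (n, amp, j), sub in grouped:
        channels: dict[str, np.ndarray] = {}
        for muscle, chan in sub.groupby("muscle"):
            idx = chan["sample_index"].to_numpy(dtype=int)
            if not np.array_equal(idx, np.arange(len(idx))):
                raise SessionIntegrityError(
                    f"sweep (n={int(n)}, I={amp:g}, j={int(j)}), muscle {muscle}: "
                    "sample_index not contiguous from 0"
                )
            channels[str(muscle)] = chan["value_uV"].to_numpy(dtype=float)
        rec = SweepRecord(int(n), float(amp), int(j), channels)
        rec.validate_groups(config)
        records.append(rec)

    _warn_gaps(records, config)
    return records


def _warn_gaps(records: Iterable[SweepRecord], config: ProtocolConfig) -> None:
    present = {r.key for r in records}
    if not present:
        return
    # only amplitudes up to the largest one seen are expected: the protocol
    # legitimately stops early at the tolerance limit
    max_amp = max(k[1] for k in present)
    expected = {
        (n, I, j)
        for n in config.electrode_positions
        for I in config.amplitude_grid_mA
        if I <= max_amp
        for j in range(1, config.repetitions_per_amplitude + 1)
    }
    gaps = sorted(expected - present)
    if gaps:
        warnings.warn(
            f"session is missing {len(gaps)} (electrode, amplitude, repetition) "
            f"sweeps: {gaps[:10]}{' ...' if len(gaps) > 10 else ''}",
            SessionGapWarning,
            stacklevel=3,
        )


def write_session(records: Iterable[SweepRecord], path) -> None:
    """Write sweeps to the long-format session CSV (inverse of
    :func:`read_session`)."""
    frames = []
    for rec in records:
        for muscle, x in rec.samples.items():
            frames.append(
                pd.DataFrame(
                    {
                        "electrode_position": rec.electrode_position,
                        "amplitude_mA": rec.amplitude_mA,
                        "repetition": rec.repetition,
                        "muscle": muscle,
                        "sample_index": np.arange(len(x)),
                        "value_uV": x,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
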