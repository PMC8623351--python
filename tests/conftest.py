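"""Shared fixtures and sweep builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tscscal import AnalysisConfig, ProtocolConfig, SweepRecord

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_sweep(
    channels: dict[str, np.ndarray],
    n: int = 1,
    I: float = 30.0,
    j: int = 1,
) -> SweepRecord:
    return SweepRecord(n, I, j, channels)


def artifact_sweep(
    onsets: tuple[int, ...],
    rng: np.random.Generator | None = None,
    n_samples: int = 600,
    noise_sd: float = 0.5,
    amp: float = 500.0,
    uniform: bool = True,
    channels: tuple[str, ...] = ("LQ", "LTS", "RQ", "RTS"),
) -> SweepRecord:
    """Sweep with 2-sample biphasic artifact spikes (+amp, -amp) at the
    given onsets, on bounded uniform noise by default (so the tail-SD
    statistics are stable and deterministic sweeps stay analyzable)."""
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        if rng is None:
            x = np.zeros(n_samples)
        elif uniform:
            x = rng.uniform(-noise_sd, noise_sd, n_samples)
        else:
            x = noise_sd * rng.standard_normal(n_samples)
        for k in onsets:
            x[k] += amp
            x[k + 1] -= amp
        out[ch] = x
    return make_sweep(out)


def noise_only_sweep(
    rng: np.random.Generator,
    n_samples: int = 600,
    noise_sd: float = 5.0,
    uniform: bool = True,
    channels: tuple[str, ...] = ("LQ", "LTS", "RQ", "RTS"),
) -> SweepRecord:
    out = {}
    for ch in channels:
        if uniform:
            out[ch] = rng.uniform(-noise_sd, noise_sd, n_samples)
        else:
            out[ch] = noise_sd * rng.standard_normal(n_samples)
    return make_sweep(out)
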