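"""Synchronizer: Laplacian detection signal, C1-C4 candidates, alignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import artifact_sweep, noise_only_sweep
from tscscal import (
    ALIGNED,
    BASELINE,
    DISCARDED,
    AnalysisConfig,
    DegenerateSweepError,
    ProtocolConfig,
    align_sweep,
    detect_first_artifact,
    double_difference,
    extract_baseline,
    synchronize,
)
from tscscal.sync import DETECTION_CHANNELS, _channel_candidates


# -- brute-force oracle ------------------------------------------------------


def oracle_candidates(raw: np.ndarray, p: int = 50, search=(9, 199), sd_factor=3.0):
    """Literal per-sample evaluation of C1-C4 for one channel."""
    n = len(raw)
    delta = np.zeros(n)
    for k in range(1, n - 1):
        delta[k] = 4.0 * (raw[k - 1] - 2.0 * raw[k] + raw[k + 1])
    tail = delta[299 : min(599, n - 1) + 1]
    thr = sd_factor * np.std(tail, ddof=1)
    any_c1 = any(abs(delta[k]) > thr for k in range(n))
    mf = raw - np.median(raw)
    cands = []
    for t in range(max(search[0], 1), search[1] + 1):
        if t + 2 * p >= n or t + 1 >= n:
            continue
        c1 = abs(delta[t]) > thr
        c2 = abs(delta[t + p]) > thr
        c3 = abs(delta[t + 2 * p]) <= thr
        c4 = (np.sign(mf[t]) != np.sign(mf[t - 1])) or (np.sign(mf[t]) != np.sign(mf[t + 1]))
        if c1 and c2 and c3 and c4:
            cands.append(t)
    return cands, any_c1


# -- double differentiation --------------------------------------------------


@pytest.mark.parametrize(
    "signal, expected",
    [
        (np.full(10, 7.3), np.zeros(10)),
        (np.arange(10, dtype=float), np.zeros(10)),  # affine: zero interior
    ],
)
def test_double_difference_annihilates_affine(signal, expected):
    np.testing.assert_allclose(double_difference(signal), expected)


def test_double_difference_impulse_stencil():
    x = np.zeros(11)
    x[5] = 1.0
    d = double_difference(x)
    np.testing.assert_allclose(d[4:7], [4.0, -8.0, 4.0])
    assert np.all(d[:4] == 0) and np.all(d[7:] == 0)


def test_double_difference_too_short():
    with pytest.raises(DegenerateSweepError):
        double_difference(np.array([1.0, 2.0]))


# -- detection ---------------------------------------------------------------


def test_detects_earliest_artifact_of_pair(protocol, cfg, rng):
    # the Laplacian stencil spreads a spike at k to k-1 (value 4A there), so
    # the earliest sample satisfying all four conditions is k-1; detection
    # must agree with the literal per-sample rule evaluation
    sweep = artifact_sweep((40, 90), rng)
    det = detect_first_artifact(sweep, protocol, cfg)
    assert det.status == ALIGNED
    assert det.onset_index in (39, 40)
    for ch in DETECTION_CHANNELS:
        cands, _ = oracle_candidates(sweep.samples[ch])
        impl, _ = _channel_candidates(sweep.samples[ch], protocol, cfg)
        assert list(impl) == cands
        assert det.onset_index == min(
            oracle_candidates(sweep.samples[c])[0][0] for c in DETECTION_CHANNELS
        )


def test_single_pulse_fails_c2_and_discards(protocol, cfg, rng):
    sweep = artifact_sweep((40,), rng)  # nothing 50 samples later
    det = detect_first_artifact(sweep, protocol, cfg)
    assert det.status == DISCARDED
    for ch in DETECTION_CHANNELS:
        cands, any_c1 = oracle_candidates(sweep.samples[ch])
        assert cands == [] and any_c1


def test_uniform_noise_is_baseline(protocol, cfg, rng):
    sweep = noise_only_sweep(rng, uniform=True)
    det = detect_first_artifact(sweep, protocol, cfg)
    assert det.status == BASELINE
    for ch in DETECTION_CHANNELS:
        _, any_c1 = oracle_candidates(sweep.samples[ch])
        assert not any_c1


def test_periodic_hits_rejected_by_c3(protocol, cfg, rng):
    # spikes at 40, 90 and 140: t=40 fails C3 (a spike also sits 100 samples
    # later), so the first accepted candidate is 90 — exactly as the
    # literal rule evaluation predicts
    sweep = artifact_sweep((40, 90, 140), rng)
    det = detect_first_artifact(sweep, protocol, cfg)
    firsts = []
    for ch in DETECTION_CHANNELS:
        cands, _ = oracle_candidates(sweep.samples[ch])
        impl, _ = _channel_candidates(sweep.samples[ch], protocol, cfg)
        assert list(impl) == cands
        if cands:
            firsts.append(cands[0])
    assert det.status == ALIGNED
    assert det.onset_index == min(firsts)
    assert det.onset_index in (89, 90)


def test_bruteforce_equivalence_on_simulated_sweeps(protocol, cfg):
    from tscscal import default_ground_truth, generate_session

    truth = default_ground_truth(7, protocol)
    records = generate_session(truth, protocol)[:40]
    for sweep in records:
        for ch in DETECTION_CHANNELS:
            cands, any_c1 = oracle_candidates(sweep.samples[ch])
            impl, impl_c1 = _channel_candidates(sweep.samples[ch], protocol, cfg)
            assert list(impl) == cands
            assert impl_c1 == any_c1


@given(shift=st.integers(min_value=-15, max_value=15))
def test_translation_equivariance(shift):
    """Shifting the sweep content shifts the detected onset identically."""
    protocol, cfg = ProtocolConfig(), AnalysisConfig()
    base_rng = np.random.default_rng(99)
    long_noise = {ch: base_rng.uniform(-0.5, 0.5, 700) for ch in ("LQ", "LTS", "RQ", "RTS")}
    onset_abs = 120

    def detect_at(start: int) -> int:
        channels = {}
        for ch, noise in long_noise.items():
            x = noise.copy()
            for k in (onset_abs, onset_abs + 50):
                x[k] += 500.0
                x[k + 1] -= 500.0
            channels[ch] = x[start : start + 600]
        from conftest import make_sweep

        det = detect_first_artifact(make_sweep(channels), protocol, cfg)
        assert det.status == ALIGNED
        return det.onset_index

    reference = detect_at(60)
    assert detect_at(60 + shift) == reference - shift


@given(scale=st.floats(min_value=1e-3, max_value=1e4))
def test_baseline_declaration_scale_invariant(scale):
    """C1 compares the signal to 3 SD of itself, so scaling cannot turn a
    baseline sweep into an artifact-bearing one."""
    protocol, cfg = ProtocolConfig(), AnalysisConfig()
    rng = np.random.default_rng(3)
    sweep = noise_only_sweep(rng, uniform=True)
    scaled = make_scaled(sweep, scale)
    assert detect_first_artifact(sweep, protocol, cfg).status == BASELINE
    assert detect_first_artifact(scaled, protocol, cfg).status == BASELINE


def make_scaled(sweep, c):
    from conftest import make_sweep

    return make_sweep({m: c * x for m, x in sweep.samples.items()})


# -- alignment ---------------------------------------------------------------


def test_align_produces_331_samples(protocol, cfg, rng):
    sweep = artifact_sweep((40, 90), rng)
    aligned = align_sweep(sweep, 40, protocol, cfg)
    assert aligned.status == ALIGNED
    assert aligned.n_samples() == 331
    assert aligned.t0_index == 30
    # t=0 holds the artifact's positive spike; second stimulus at exactly +50 ms
    assert aligned.samples["LQ"][30] > 400
    assert aligned.samples["LQ"][30 + protocol.inter_pulse_samples] > 400
    np.testing.assert_allclose(aligned.time_ms()[[0, 30, 330]], [-30.0, 0.0, 300.0])


def test_baseline_extraction_keeps_first_331(protocol, cfg, rng):
    sweep = noise_only_sweep(rng, uniform=True)
    b = extract_baseline(sweep, protocol, cfg)
    assert b.status == BASELINE and b.n_samples() == 331
    np.testing.assert_array_equal(b.samples["RQ"], sweep.samples["RQ"][:331])


def test_onset_too_close_to_edge_discards(protocol, cfg, rng):
    sweep = artifact_sweep((20, 70), rng)
    assert align_sweep(sweep, 20, protocol, cfg).status == DISCARDED
    short = artifact_sweep((40, 90), rng, n_samples=320)
    assert align_sweep(short, 40, protocol, cfg).status == DISCARDED


def test_realignment_is_idempotent(protocol, cfg, rng):
    sweep = artifact_sweep((40, 90), rng)
    first = synchronize(sweep, protocol, cfg)
    assert first.status == ALIGNED
    again = synchronize(
        type(sweep)(1, 30.0, 1, dict(first.samples)), protocol, cfg
    )
    # re-detection on the cropped sweep finds the artifact at index 30 and
    # cannot crop further left than sample 0
    assert again.status in (ALIGNED, DISCARDED)
    if again.status == ALIGNED:
        np.testing.assert_array_equal(again.samples["LQ"], first.samples["LQ"])
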