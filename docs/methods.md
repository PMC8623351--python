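# Methods

This note documents the signal-processing model, the tunable parameters,
the synthetic-session generator, and the numerical/design choices made
where the procedure left room.

## Signal model and procedure

A calibration session applies double stimuli (inter-pulse interval
p = 50 ms) at electrode positions n and amplitudes I on a fixed grid,
recording ~600 ms raw EMG sweeps at 1 kHz from two quadriceps (LQ, RQ)
and two triceps surae (LTS, RTS) channels. Two physiological facts drive
the analysis:

* a posterior root-muscle (PRM) reflex — the desired response for
  sub-threshold tSCS therapy — exhibits strong post-activation
  depression: the response to the second pulse delivered 50 ms after the
  first is heavily attenuated;
* a direct motor response (M-wave), elicited by stimulating efferent
  axons, shows no such depression.

The suppression ratio sup = clip(1 − amp2/amp1, 0, 1), computed from
peak-to-peak amplitudes in the 10–45 ms windows after each pulse,
therefore discriminates reflex (sup > 0.60) from presumed M-wave.

### Assumptions

* The stimulation artifact is the dominant fast transient in the
  quadriceps channels; its double-differentiated (Laplacian) magnitude
  exceeds 3 SD of the late-sweep Laplacian, while evoked responses and
  noise mostly do not.
* The late window (raw samples ≥ 300; t ≥ 100 ms after alignment)
  contains no evoked activity and represents rest EMG.
* Channels of one sensor share a clock; the two sensors are aligned by a
  single onset (see tie rule below).
* Units are fixed: µV for EMG, mA for stimulation. The 50 µV response
  gate is absolute, so no auto-scaling is performed anywhere.

## Parameters

All values live in `ProtocolConfig` / `AnalysisConfig` and are
overridable; defaults are the standard operating point.

| parameter | default | meaning |
|---|---|---|
| amplitude grid | 5…75 mA, step 5 | protocol ramp; also the rounding grid for the therapy amplitude |
| inter-pulse interval | 50 ms | paired-pulse spacing; C2/C3 offsets scale with it (p and 2p samples) |
| artifact search window | samples 9–199 (0-based) | where the first stimulus may occur |
| tail window | samples 299–599 | reference for the 3·SD artifact gate |
| crop window | −30…300 ms | aligned sweep, 331 samples at 1 kHz |
| blank windows | −2…2, 48…52 ms | artifact removal (set to 0, restored after filtering) |
| band-stop | 43–47 Hz, order 2 | interference notch, Butterworth, zero-phase |
| low-pass | 300 Hz, order 1 | Butterworth, zero-phase; requires fs > 600 Hz |
| noise window | 100…300 ms | per-muscle base noise emḡᵢ (sample SD, pooled session-wide) |
| similarity windows / factor | 5–45 ∪ 55–95 ms / 16 | repetitions similar iff pairwise RMSE < 16·emḡᵢ |
| averaging window | −1…200 ms | 202-sample mean response |
| response gates | 50 µV and 6·emḡᵢ | both must be exceeded (strictly) for a response |
| suppression threshold | 0.60 | strict ">" separates green from yellow |
| therapy fraction / rounding | 0.9 / grid floor | sub-threshold guarantee: therapy < I′ |
| minimal requirement | 2 green muscles | candidate gate of the ranking method |

## Numerical choices

* **Zero phase.** "Non-causal" filtering is realized as forward–backward
  (`sosfiltfilt`) application, doubling the effective order but leaving
  response latencies in the 10–45 ms windows untouched. Band-stop and
  low-pass are fused into one SOS cascade.
* **Laplacian edges.** The first and last sample of the Δ-signal have no
  valid stencil and are set to 0; candidates are restricted to samples
  9–199, so edges never matter.
* **SD convention.** Sample standard deviation (ddof = 1) throughout
  (artifact gate and noise profile).
* **Window conversion.** Windows are specified in ms and converted by
  rounding each boundary to the nearest sample; all intervals are closed.
  Configuration validation rejects amplitude windows that would overlap
  the blanked intervals (which would silently measure restored zeros).
* **Detection ties.** Detection runs on LQ and RQ only; the earlier
  onset across the two channels wins, LQ on an exact tie. The earliest
  candidate of a clean two-sample biphasic artifact at sample k is k−1
  (the stencil spreads the spike), a deliberate property of the rule set
  that is irrelevant at ms scale.
* **No padding.** A sweep whose −30…300 ms window does not fit inside
  the recording is discarded; downstream windows must hold real data.
* **Sign test (C4).** Uses `np.sign` on the median-free signal; a zero
  sample counts as a sign change against any nonzero neighbor.
* **Similarity subsets.** For ≤ 3 repetitions the largest mutually
  similar subset is found by exhaustive enumeration; equal-size ties go
  to the lowest repetition indices (determinism).
* **Degenerate suppression.** amp1 = 0 yields sup = 0 and is flagged via
  `suppression_defined=False`; classification is unaffected (such cells
  are gray through the amplitude gates).
* **Cost ties.** The globally maximal J wins; residual ties break toward
  lower amplitude, then the more caudal (lower) electrode.
* **Therapy rounding.** Grid flooring (largest grid value ≤ 0.9·I′)
  reproduces the canonical worked example (40 mA → 35 mA) and guarantees
  sub-threshold stimulation; `rounding="none"` returns 0.9·I′ exactly.
  If 0.9·I′ falls below the lowest grid value the unrounded target is
  returned rather than rounding *up* to an amplitude ≥ I′.

## Open design points and how they were resolved

* **Baseline-only cells.** Cells with fewer than two aligned repetitions
  but at least two artifact-free (baseline) repetitions are gated and
  averaged on the baseline sweeps' nominal time axis; they evaluate as
  no-response. "Invalid" is reserved for failed similarity or fewer than
  two usable repetitions of either kind.
* **Noise profile scope.** The pooled SD uses every aligned and baseline
  filtered sweep; discarded sweeps are excluded. No second pass excludes
  repetitions later dropped by the similarity gate (the gate needs the
  profile first).
* **Per-electrode threshold.** I′(n) is defined by the first green label
  in *any* muscle at position n, and the ranking's priority 3 uses that
  per-electrode value.
* **Session storage.** Long-format CSV with 0-based `sample_index`, one
  row per sample; a deliberate artifact of this implementation, not of
  the procedure.
* **43–47 Hz band-stop.** Implemented as specified even though European
  mains is 50 Hz; the corner frequencies are configurable.

## The synthetic-session generator

`tscscal.simulate` produces sessions with known ground truth to exercise
every pipeline branch:

* two-sample biphasic artifact spikes (+A, −A; default A = 500 µV) at a
  per-sweep onset jittered uniformly over samples 30–80, and again one
  inter-pulse interval later — the Laplacian detector, including the
  sign-change test, is genuinely exercised;
* evoked responses as Gaussian-windowed single-cycle sine wavelets
  (~8 ms wide, onset latency 12–25 ms) whose peak-to-peak amplitude
  follows a sigmoid recruitment curve over stimulation amplitude
  (midpoint = threshold, slope 1 mA, saturation 600 µV); the second
  response is scaled by 1 − suppression (0.85 for reflex sites, 0.05 for
  M-wave sites);
* Gaussian white noise (SD 5 µV) plus an optional 45 Hz line component;
* occasional movement-corrupted repetitions (default: 5 % of cells get
  one): a 1 mV, 8 Hz burst confined to the response epoch. Constant
  offsets would be removed by median subtraction, and a full-sweep
  oscillation would contaminate the late noise window, so a
  stimulus-triggered transient is both the realistic and the
  discriminating choice.

`default_ground_truth` lays out a session with one best electrode
(reflexes in all four muscles at low thresholds on the grid), weaker
neighbors (a quadriceps reflex pair plus one M-wave at higher
thresholds) and silent remote positions; `quiet=True` yields a
no-response session (artifacts present, no evoked activity).

### What the generator does and does not emulate

It reproduces the features the pipeline's decisions depend on: artifact
timing and sharpness, recruitment thresholds aligned to the grid,
paired-pulse suppression contrast, electrode-dependent muscle
recruitment, corrupted repetitions. It does **not** model volume
conduction, motor-unit statistics, non-stationary or heavy-tailed EMG
noise, latency jitter across repetitions, or gradual recruitment between
grid points. Passing recovery tests therefore demonstrates correctness
of the decision chain under the stated signal model, not clinical
performance on real recordings.

Two consequences of the exact published rules are worth knowing:

* **Baseline is practically unreachable for Gaussian noise.** Declaring
  a sweep baseline requires C1 to fail at *every* sample, but the
  maximum |Δ| of ~600 Gaussian samples essentially always exceeds 3 SD.
  Artifact-free *bounded* noise (e.g. uniform) is declared baseline
  reliably — its Laplacian maximum is below 3 SD of itself — which is
  what the baseline-branch tests use. No-response sessions are instead
  modeled with artifacts present and no evoked activity, which matches
  how such participants present in practice.
* **Rare misalignments at high response amplitudes.** C2 can latch onto
  a strong evoked response 50 samples downstream of a noise sample that
  happens to pass C1/C4, occasionally misaligning or discarding a
  repetition (~1–3 % of sweeps). The similarity gate rejects misaligned
  repetitions on responding muscles; on silent muscles the two-sample
  unblanked artifact residue can sit just below the 16·emḡ RMSE gate and
  produce an isolated spurious yellow cell. Recovery tests bound the
  effect (≥ 95 % cell accuracy with exact threshold recovery over 20
  seeds).

## Problem sizes used in the tests

End-to-end recovery runs 20 seeded sessions of the full default protocol
(4 electrodes × 15 amplitudes × 3 repetitions = 180 four-channel sweeps
each); oracle comparisons use 1000 randomized small rating matrices and
per-sample rule evaluation on ~34 sweeps; property tests run 50
derandomized examples each. The whole suite completes in well under a
minute on one CPU.
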