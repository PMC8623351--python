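# tscscal

Automated calibration of **transcutaneous spinal cord stimulation (tSCS)**
from multi-muscle evoked EMG.

Sub-threshold tSCS for spasticity control requires choosing, per patient,
the paraspinal electrode position and a stimulation amplitude just below
the reflex threshold. `tscscal` implements the complete calibration
pipeline for the standard paired-pulse, multi-electrode, amplitude-ramp
protocol: for each electrode position *n* ∈ {1..4} (caudal→rostral), each
amplitude *I* = 5, 10, …, ≤ 75 mA and repetition *j* ∈ {1, 2, 3}, a double
stimulus (50 ms inter-pulse interval) is applied while EMG is sampled at
1 kHz from left/right quadriceps (LQ/RQ) and triceps surae (LTS/RTS).

The library is the primary interface; a thin CLI (`tscscal simulate |
calibrate | report`) and narrative scripts under `examples/` sit on top.

## Pipeline

1. **Synchronization** — the wireless sensors are not hardware-triggered,
   so the first stimulus is located from its artifact. The raw quadriceps
   signals are double-differentiated with a discrete Laplacian,
   `Δx[k] = 4(x[k−1] − 2x[k] + x[k+1])`, and a sample *t\** is an artifact
   candidate iff
   * C1: |Δx(t\*)| > 3·SD(Δx over the late tail window),
   * C2: |Δx(t\* + 50)| > 3·SD(·)  (the second pulse),
   * C3: |Δx(t\* + 100)| ≤ 3·SD(·)  (rejects periodic hits),
   * C4: the median-free raw signal changes sign at *t\**.

   The earliest candidate becomes *t* = 0 and the sweep is cropped to
   −30…300 ms (331 samples). Sweeps where C1 never fires are *baseline*
   (artifact-free); sweeps with no full candidate are discarded.
2. **Pre-filtering** — median removal, artifact blanking at −2…2 ms and
   48…52 ms, a 2nd-order Butterworth band-stop (43–47 Hz) and 1st-order
   low-pass (300 Hz), both applied forward–backward (zero phase), then
   re-blanking.
3. **Noise profile** — per-muscle base noise `emḡᵢ` = SD of all filtered
   samples with 100 ≤ t ≤ 300 ms, pooled over the whole session.
4. **Similarity gating and averaging** — repetitions are compared by the
   RMSE over 5–45 ∪ 55–95 ms; a pair is similar iff RMSE < 16·`emḡᵢ`. The
   largest mutually similar subset (≥ 2) is averaged on −1…200 ms; else
   the cell is **invalid**.
5. **Rating** — peak-to-peak amplitudes `amp1`, `amp2` in the 10–45 ms
   windows after each pulse; paired-pulse suppression
   `sup = clip(1 − amp2/amp1, 0, 1)` exploits post-activation depression
   of posterior root-muscle reflexes. Each (muscle, *n*, *I*) cell gets a
   color: **gray** (no response: amp1 ≤ 6·`emḡᵢ` or ≤ 50 µV), **green**
   (reflex: above both gates and sup > 60 %), **yellow** (presumed M-wave:
   above both gates, sup ≤ 60 %), **red** (invalid).
6. **Recommendation** — two independent methods:
   * *Ranking*: pairs with ≥ 2 greens, ordered by (most greens, smallest
     I − I′(n), lowest I), where I′(n) is the electrode's amplitude
     threshold (first green at *n*);
   * *Cost function*: `J(n, I) = ¼ Σᵢ (amp1ᵢ / amp̄1ᵢ) · supᵢ`, with amp̄1ᵢ
     the per-muscle maximum; the electrode with the globally largest *J*
     wins.

   Both suggest a therapy amplitude of **90 % of I′** of the selected
   electrode, floored to the amplitude grid (I′ = 40 mA → 0.9·40 = 36 →
   **35 mA** on the 5 mA grid).

## Worked example

```bash
python examples/01_simulate_and_calibrate.py
```

```
simulated 180 sweeps (4 electrodes x 15 amplitudes x 3 repetitions)
sweep dispositions: {'aligned': 177, 'discarded': 3}
invalid cells: 0.0%
base noise level per muscle [uV]: {'LQ': 3.4, 'LTS': 4.3, 'RQ': 3.5, 'RTS': 3.4}

ranking approach: electrode n=2, I'=30 mA -> therapy 25 mA
cost approach:    electrode n=2, I'=30 mA -> therapy 25 mA
methods agree on the electrode: True
```

The simulated session's ground truth places reflex responses for all four
muscles at electrode 2 with recruitment thresholds starting at 30 mA; the
pipeline recovers the electrode, the amplitude threshold I′ = 30 mA and
suggests the sub-threshold therapy amplitude 25 mA (90 % of 30, floored
to the grid). `examples/02_rating_report.py` prints the rating-light
matrix (one glyph per muscle and cell) and the rating-details table with
ranks and cost values; `examples/03_suppression_and_rating.py` walks
through the suppression statistic and classification gates.

The same flow from a shell:

```bash
tscscal simulate --seed 1 --out session.csv --truth-out truth.json
tscscal calibrate --input session.csv --out report/
tscscal report --in report/report.json
```

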