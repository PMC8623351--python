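"""Simulate a calibration session and run the full pipeline on it.

Generates a four-electrode, 5..75 mA amplitude-ramp session with a known
ground-truth best electrode, then runs artifact synchronization,
filtering, similarity gating, rating and both recommendation methods.
"""

from tscscal import (
    ProtocolConfig,
    calibrate_session,
    default_ground_truth,
    generate_session,
)

protocol = ProtocolConfig()
truth = default_ground_truth(seed=1, protocol=protocol)
records = generate_session(truth, protocol)
print(f"simulated {len(records)} sweeps "
      f"({len(protocol.electrode_positions)} electrodes x "
      f"{len(protocol.amplitude_grid_mA)} amplitudes x 3 repetitions)")

result = calibrate_session(records, protocol)

print("sweep dispositions:", result.disposition_counts())
print(f"invalid cells: {100 * result.invalid_cell_ratio:.1f}%")
print("base noise level per muscle [uV]:",
      {m: round(v, 1) for m, v in result.noise.level_uV.items()})

rec = result.recommendation
print(f"\nranking approach: electrode n={rec.ranking.electrode_position}, "
      f"I'={rec.ranking.threshold_mA:g} mA -> therapy {rec.ranking.therapy_amplitude_mA:g} mA")
print(f"cost approach:    electrode n={rec.cost.electrode_position}, "
      f"I'={rec.cost.threshold_mA:g} mA -> therapy {rec.cost.therapy_amplitude_mA:g} mA")
print("methods agree on the electrode:", rec.agree)

# The therapy amplitude is 90% of the amplitude threshold I' (the lowest
# stimulation amplitude that elicited a reflex at the chosen electrode),
# floored to the 5 mA grid, guaranteeing sub-threshold stimulation.
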