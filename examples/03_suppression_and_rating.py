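"""Paired-pulse suppression and the four-color rating rules, step by step.

A posterior root-muscle reflex shows strong post-activation depression:
its response to the second pulse of a 50 ms double stimulus is much
smaller than to the first.  A direct motor response (M-wave) is not
suppressed.  The suppression ratio sup = 1 - amp2/amp1 (clipped to [0,1])
separates the two.
"""

from tscscal import (
    AnalysisConfig,
    ProtocolConfig,
    ResponseFeatures,
    classify,
    suppression,
    therapy_amplitude,
)

cfg = AnalysisConfig()
noise_level = 5.0  # uV, muscle-specific base noise (SD of late-window EMG)

cases = [
    ("complete suppression", 400.0, 0.0),
    ("typical reflex", 300.0, 45.0),
    ("M-wave (no depression)", 300.0, 285.0),
    ("sub-threshold / noise", 20.0, 18.0),
]
for name, amp1, amp2 in cases:
    sup = suppression(amp1, amp2)
    label = classify(ResponseFeatures(amp1, amp2, sup), noise_level, cfg)
    print(f"{name:>25s}: amp1={amp1:5.0f} uV amp2={amp2:5.0f} uV "
          f"sup={sup:.2f} -> {label.value} ({label.color})")

# A response counts only if amp1 exceeds BOTH 50 uV and 6x the base noise;
# among responses, sup > 0.60 marks a reflex (green), else presumed M-wave.

protocol = ProtocolConfig()
threshold = 40.0  # lowest amplitude with a first green label at the electrode
print(f"\namplitude threshold I' = {threshold:g} mA -> therapy amplitude "
      f"{therapy_amplitude(threshold, protocol, cfg):g} mA "
      f"(90% of I', floored to the 5 mA grid)")
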