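{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Simulated-session ground truth ledger",
  "type": "object",
  "required": ["sites", "noise_sd_uV", "artifact_amp_uV", "seed"],
  "properties": {
    "sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["muscle", "electrode_position", "response_type"],
        "properties": {
          "muscle": {"type": "string"},
          "electrode_position": {"type": "integer"},
          "response_type": {"type": "string", "enum": ["reflex", "m_wave", "none"]},
          "threshold_mA": {"type": "number", "minimum": 0},
          "suppression": {"type": "number", "minimum": 0},
          "latency_ms": {"type": "number", "minimum": 0},
          "max_amp_uV": {"type": "number", "minimum": 0}
        }
      }
    },
    "noise_sd_uV": {"type": "number", "minimum": 0},
    "artifact_amp_uV": {"type": "number", "minimum": 0},
    "mains_45hz_uV": {"type": "number", "minimum": 0},
    "corrupted_rate": {"type": "number", "minimum": 0},
    "corruption_amp_uV": {"type": "number", "minimum": 0},
    "recruitment_slope_mA": {"type": "number", "minimum": 0},
    "seed": {"type": "integer"}
  }
}
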