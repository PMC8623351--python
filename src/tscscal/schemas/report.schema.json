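{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "tSCS calibration report",
  "type": "object",
  "required": [
    "schema_version",
    "cells",
    "thresholds",
    "ranking",
    "costs",
    "recommendation"
  ],
  "properties": {
    "schema_version": {
      "type": "integer",
      "minimum": 1
    },
    "protocol": {
      "type": "object"
    },
    "noise_profile_uV": {
      "type": "object"
    },
    "cells": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "muscle",
          "electrode_position",
          "amplitude_mA",
          "label",
          "color"
        ],
        "properties": {
          "muscle": {
            "type": "string"
          },
          "electrode_position": {
            "type": "integer"
          },
          "amplitude_mA": {
            "type": "number"
          },
          "label": {
            "type": "string",
            "enum": [
              "no_response",
              "reflex",
              "m_wave",
              "invalid"
            ]
          },
          "color": {
            "type": "string",
            "enum": [
              "gray",
              "green",
              "yellow",
              "red"
            ]
          },
          "amp1_uV": {
            "type": [
              "number",
              "null"
            ]
          },
          "amp2_uV": {
            "type": [
              "number",
              "null"
            ]
          },
          "suppression": {
            "type": [
              "number",
              "null"
            ]
          },
          "reason": {
            "type": [
              "string",
              "null"
            ]
          }
        }
      }
    },
    "thresholds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "electrode_position",
          "threshold_mA"
        ],
        "properties": {
          "electrode_position": {
            "type": "integer"
          },
          "threshold_mA": {
            "type": [
              "number",
              "null"
            ]
          }
        }
      }
    },
    "ranking": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "rank",
          "electrode_position",
          "amplitude_mA",
          "green_count"
        ],
        "properties": {
          "rank": {
            "type": "integer",
            "minimum": 1
          },
          "electrode_position": {
            "type": "integer"
          },
          "amplitude_mA": {
            "type": "number"
          },
          "green_count": {
            "type": "integer",
            "minimum": 0
          }
        }
      }
    },
    "costs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "electrode_position",
          "amplitude_mA",
          "J"
        ],
        "properties": {
          "electrode_position": {
            "type": "integer"
          },
          "amplitude_mA": {
            "type": "number"
          },
          "J": {
            "type": "number",
            "minimum": 0
          }
        }
      }
    },
    "normalizers_uV": {
      "type": "object"
    },
    "recommendation": {
      "type": "object",
      "required": [
        "ranking",
        "cost",
        "agree"
      ],
      "properties": {
        "ranking": {
          "type": "object",
          "required": [
            "electrode_position",
            "threshold_mA",
            "therapy_amplitude_mA"
          ],
          "properties": {
            "electrode_position": {
              "type": [
                "integer",
                "null"
              ]
            },
            "threshold_mA": {
              "type": [
                "number",
                "null"
              ]
            },
            "therapy_amplitude_mA": {
              "type": [
                "number",
                "null"
              ]
            },
            "reason": {
              "type": [
                "string",
                "null"
              ]
            }
          }
        },
        "cost": {
          "type": "object",
          "required": [
            "electrode_position",
            "threshold_mA",
            "therapy_amplitude_mA"
          ],
          "properties": {
            "electrode_position": {
              "type": [
                "integer",
                "null"
              ]
            },
            "threshold_mA": {
              "type": [
                "number",
                "null"
              ]
            },
            "therapy_amplitude_mA": {
              "type": [
                "number",
                "null"
              ]
            },
            "reason": {
              "type": [
                "string",
                "null"
              ]
            }
          }
        },
        "agree": {
          "type": [
            "boolean",
            "null"
          ]
        }
      }
    },
    "quality": {
      "type": "object"
    }
  }
}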