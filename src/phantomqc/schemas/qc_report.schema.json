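{
  "$defs": {
    "MotionReport": {
      "additionalProperties": false,
      "properties": {
        "max_rotation_deg": {
          "title": "Max Rotation Deg",
          "type": "number"
        },
        "max_translation_mm": {
          "title": "Max Translation Mm",
          "type": "number"
        },
        "rotation_limit_deg": {
          "default": 0.1,
          "title": "Rotation Limit Deg",
          "type": "number"
        },
        "rotation_ok": {
          "default": true,
          "title": "Rotation Ok",
          "type": "boolean"
        },
        "translation_limit_mm": {
          "default": 0.1,
          "title": "Translation Limit Mm",
          "type": "number"
        },
        "translation_ok": {
          "default": true,
          "title": "Translation Ok",
          "type": "boolean"
        }
      },
      "required": [
        "max_translation_mm",
        "max_rotation_deg"
      ],
      "title": "MotionReport",
      "type": "object"
    },
    "ROIReport": {
      "additionalProperties": false,
      "description": "Per-ROI scalar metrics.",
      "properties": {
        "center": {
          "maxItems": 3,
          "minItems": 3,
          "prefixItems": [
            {
              "type": "integer"
            },
            {
              "type": "integer"
            },
            {
              "type": "integer"
            }
          ],
          "title": "Center",
          "type": "array"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "n_pixels": {
          "title": "N Pixels",
          "type": "integer"
        },
        "sfnr": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Sfnr"
        },
        "side": {
          "title": "Side",
          "type": "integer"
        },
        "signal": {
          "title": "Signal",
          "type": "number"
        },
        "snr": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Snr"
        },
        "static_noise_per_timepoint": {
          "title": "Static Noise Per Timepoint",
          "type": "number"
        },
        "static_spatial_noise": {
          "title": "Static Spatial Noise",
          "type": "number"
        },
        "tfn": {
          "title": "Tfn",
          "type": "number"
        }
      },
      "required": [
        "label",
        "center",
        "side",
        "n_pixels",
        "signal",
        "static_spatial_noise",
        "static_noise_per_timepoint",
        "tfn",
        "sfnr",
        "snr"
      ],
      "title": "ROIReport",
      "type": "object"
    }
  },
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "additionalProperties": false,
  "description": "Serializable summary of all QC metrics for one series.",
  "properties": {
    "TR_ms": {
      "title": "Tr Ms",
      "type": "number"
    },
    "background_roi_centers": {
      "anyOf": [
        {
          "additionalProperties": {
            "maxItems": 3,
            "minItems": 3,
            "prefixItems": [
              {
                "type": "integer"
              },
              {
                "type": "integer"
              },
              {
                "type": "integer"
              }
            ],
            "type": "array"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Background Roi Centers"
    },
    "baseline_range": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Baseline Range"
    },
    "baseline_stability_pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Baseline Stability Pct"
    },
    "config_sha256": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Config Sha256"
    },
    "detection_threshold_k": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Detection Threshold K"
    },
    "ghosting_ratio_pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ghosting Ratio Pct"
    },
    "ghosting_ratio_se_pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ghosting Ratio Se Pct"
    },
    "kspace_max_variation": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Kspace Max Variation"
    },
    "motion": {
      "anyOf": [
        {
          "$ref": "#/$defs/MotionReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "n_actual": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Actual"
    },
    "n_theoretical": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Theoretical"
    },
    "n_volumes": {
      "title": "N Volumes",
      "type": "integer"
    },
    "psc_pct": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Psc Pct"
    },
    "rois": {
      "items": {
        "$ref": "#/$defs/ROIReport"
      },
      "title": "Rois",
      "type": "array"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "sensitivity_pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Sensitivity Pct"
    },
    "voxel_size_mm": {
      "maxItems": 3,
      "minItems": 3,
      "prefixItems": [
        {
          "type": "number"
        },
        {
          "type": "number"
        },
        {
          "type": "number"
        }
      ],
      "title": "Voxel Size Mm",
      "type": "array"
    }
  },
  "required": [
    "n_volumes",
    "TR_ms",
    "voxel_size_mm",
    "rois"
  ],
  "title": "phantomqc QC report",
  "type": "object"
}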