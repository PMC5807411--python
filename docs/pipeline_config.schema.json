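{
  "additionalProperties": false,
  "description": "Validated configuration of one full pipeline run.\n\nUnknown keys are rejected; the JSON schema is available through\n``PipelineConfig.model_json_schema()``.",
  "properties": {
    "tissue_model": {
      "default": "native",
      "enum": [
        "native",
        "engineered",
        "digested"
      ],
      "title": "Tissue Model",
      "type": "string"
    },
    "n_rows": {
      "anyOf": [
        {
          "minimum": 1,
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Rows"
    },
    "n_cols": {
      "anyOf": [
        {
          "minimum": 1,
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Cols"
    },
    "pixel_size_um": {
      "anyOf": [
        {
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Pixel Size Um"
    },
    "axis_lo": {
      "default": 350.0,
      "exclusiveMinimum": 0,
      "title": "Axis Lo",
      "type": "number"
    },
    "axis_hi": {
      "default": 3600.0,
      "title": "Axis Hi",
      "type": "number"
    },
    "axis_step": {
      "default": 5.0,
      "exclusiveMinimum": 0,
      "title": "Axis Step",
      "type": "number"
    },
    "baseline_amplitude": {
      "default": 20.0,
      "minimum": 0,
      "title": "Baseline Amplitude",
      "type": "number"
    },
    "noise_frac": {
      "default": 0.02,
      "minimum": 0,
      "title": "Noise Frac",
      "type": "number"
    },
    "noise_floor": {
      "default": 0.0,
      "minimum": 0,
      "title": "Noise Floor",
      "type": "number"
    },
    "lateral_cv": {
      "anyOf": [
        {
          "minimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Lateral Cv"
    },
    "include_cells": {
      "default": false,
      "title": "Include Cells",
      "type": "boolean"
    },
    "baseline_method": {
      "default": "rolling_shape",
      "enum": [
        "rolling_shape",
        "asymmetric_ls"
      ],
      "title": "Baseline Method",
      "type": "string"
    },
    "baseline_window_points": {
      "default": 1000,
      "minimum": 3,
      "title": "Baseline Window Points",
      "type": "integer"
    },
    "fit_lo": {
      "default": 800.0,
      "title": "Fit Lo",
      "type": "number"
    },
    "fit_hi": {
      "default": 1800.0,
      "title": "Fit Hi",
      "type": "number"
    },
    "k": {
      "default": 4,
      "minimum": 1,
      "title": "K",
      "type": "integer"
    },
    "init": {
      "default": "reference",
      "enum": [
        "reference",
        "purest_pixel",
        "seeded_random"
      ],
      "title": "Init",
      "type": "string"
    },
    "merge_threshold": {
      "default": 0.9,
      "exclusiveMinimum": 0,
      "maximum": 1,
      "title": "Merge Threshold",
      "type": "number"
    },
    "max_iter": {
      "default": 200,
      "minimum": 1,
      "title": "Max Iter",
      "type": "integer"
    },
    "tol": {
      "default": 1e-06,
      "exclusiveMinimum": 0,
      "title": "Tol",
      "type": "number"
    },
    "water_band_lo": {
      "default": 3100.0,
      "title": "Water Band Lo",
      "type": "number"
    },
    "water_band_hi": {
      "default": 3600.0,
      "title": "Water Band Hi",
      "type": "number"
    },
    "n_sections": {
      "anyOf": [
        {
          "minimum": 2,
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Sections"
    },
    "assay_noise_cv": {
      "default": 0.08,
      "minimum": 0,
      "title": "Assay Noise Cv",
      "type": "number"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    }
  },
  "title": "PipelineConfig",
  "type": "object"
}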