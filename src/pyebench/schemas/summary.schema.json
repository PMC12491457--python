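{
  "$defs": {
    "LevelSummary": {
      "properties": {
        "level": {
          "title": "Level",
          "type": "string"
        },
        "n_runs": {
          "title": "N Runs",
          "type": "integer"
        },
        "ids_total": {
          "title": "Ids Total",
          "type": "integer"
        },
        "ids_by_species": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Ids By Species",
          "type": "object"
        },
        "completeness": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Completeness",
          "type": "object"
        },
        "ids_per_minute": {
          "title": "Ids Per Minute",
          "type": "number"
        },
        "median_cv_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Median Cv Percent"
        },
        "median_rt_cv_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Median Rt Cv Percent"
        },
        "accuracy": {
          "additionalProperties": {
            "type": "number"
          },
          "default": {},
          "title": "Accuracy",
          "type": "object"
        },
        "precision": {
          "additionalProperties": {
            "type": "number"
          },
          "default": {},
          "title": "Precision",
          "type": "object"
        },
        "missingness_crossing_rank": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Missingness Crossing Rank"
        }
      },
      "required": [
        "level",
        "n_runs",
        "ids_total",
        "ids_by_species",
        "completeness",
        "ids_per_minute"
      ],
      "title": "LevelSummary",
      "type": "object"
    },
    "SetupSummary": {
      "properties": {
        "setup_id": {
          "title": "Setup Id",
          "type": "string"
        },
        "acquisition_mode": {
          "title": "Acquisition Mode",
          "type": "string"
        },
        "gradient_length": {
          "title": "Gradient Length",
          "type": "number"
        },
        "levels": {
          "items": {
            "$ref": "#/$defs/LevelSummary"
          },
          "title": "Levels",
          "type": "array"
        }
      },
      "required": [
        "setup_id",
        "acquisition_mode",
        "gradient_length",
        "levels"
      ],
      "title": "SetupSummary",
      "type": "object"
    }
  },
  "properties": {
    "schema_version": {
      "default": 1,
      "title": "Schema Version",
      "type": "integer"
    },
    "package_version": {
      "default": "0.1.0",
      "title": "Package Version",
      "type": "string"
    },
    "generated_at": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Generated At"
    },
    "design_levels": {
      "items": {
        "type": "string"
      },
      "title": "Design Levels",
      "type": "array"
    },
    "filter_audit": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "integer"
        },
        "type": "object"
      },
      "title": "Filter Audit",
      "type": "object"
    },
    "setups": {
      "items": {
        "$ref": "#/$defs/SetupSummary"
      },
      "title": "Setups",
      "type": "array"
    }
  },
  "required": [
    "design_levels",
    "filter_audit",
    "setups"
  ],
  "title": "EvaluationSummary",
  "type": "object"
}
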