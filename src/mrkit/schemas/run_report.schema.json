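{
  "$defs": {
    "AnalysisBlock": {
      "description": "Estimates plus sensitivity results for one instrument set.",
      "properties": {
        "k": {
          "title": "K",
          "type": "integer"
        },
        "estimates": {
          "additionalProperties": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Estimates",
          "type": "object"
        },
        "heterogeneity": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Heterogeneity"
        },
        "presso": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Presso"
        },
        "loo": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Loo"
        }
      },
      "required": [
        "k",
        "estimates"
      ],
      "title": "AnalysisBlock",
      "type": "object"
    },
    "StageCount": {
      "properties": {
        "stage": {
          "title": "Stage",
          "type": "string"
        },
        "offered": {
          "title": "Offered",
          "type": "integer"
        },
        "kept": {
          "title": "Kept",
          "type": "integer"
        },
        "dropped": {
          "title": "Dropped",
          "type": "integer"
        },
        "details": {
          "additionalProperties": true,
          "title": "Details",
          "type": "object"
        }
      },
      "required": [
        "stage",
        "offered",
        "kept",
        "dropped"
      ],
      "title": "StageCount",
      "type": "object"
    }
  },
  "description": "Consolidated, schema-validated record of one pipeline run.",
  "properties": {
    "software": {
      "default": "mrkit",
      "title": "Software",
      "type": "string"
    },
    "version": {
      "default": "0.1.0",
      "title": "Version",
      "type": "string"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageCount"
      },
      "title": "Stages",
      "type": "array"
    },
    "harmonization": {
      "additionalProperties": true,
      "title": "Harmonization",
      "type": "object"
    },
    "primary": {
      "anyOf": [
        {
          "$ref": "#/$defs/AnalysisBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "post_outlier": {
      "anyOf": [
        {
          "$ref": "#/$defs/AnalysisBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "confounder_filtered": {
      "anyOf": [
        {
          "$ref": "#/$defs/AnalysisBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "confounder_filtered_post_outlier": {
      "anyOf": [
        {
          "$ref": "#/$defs/AnalysisBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "mvmr": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Mvmr",
      "type": "array"
    },
    "power": {
      "additionalProperties": true,
      "title": "Power",
      "type": "object"
    },
    "errors": {
      "items": {
        "type": "string"
      },
      "title": "Errors",
      "type": "array"
    }
  },
  "title": "RunReport",
  "type": "object"
}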