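{
  "$defs": {
    "RegionConfig": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "lo": {
          "title": "Lo",
          "type": "number"
        },
        "hi": {
          "title": "Hi",
          "type": "number"
        }
      },
      "required": [
        "label",
        "lo",
        "hi"
      ],
      "title": "RegionConfig",
      "type": "object"
    }
  },
  "description": "Validated configuration for :func:`run_pipeline`.\n\nAll defaults are explicit; the JSON schema is exported with the package\n(``ipapfesta/schemas/analysis_config.schema.json``).",
  "properties": {
    "ip_path": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ip Path"
    },
    "ap_path": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ap Path"
    },
    "scan_paths": {
      "items": {
        "type": "string"
      },
      "title": "Scan Paths",
      "type": "array"
    },
    "interleave_layout": {
      "default": "IP_AP_alternating",
      "enum": [
        "IP_AP_alternating",
        "blocks"
      ],
      "title": "Interleave Layout",
      "type": "string"
    },
    "spectrum_format": {
      "default": "csv",
      "enum": [
        "csv",
        "jcamp"
      ],
      "title": "Spectrum Format",
      "type": "string"
    },
    "k_policy": {
      "default": "optimize",
      "enum": [
        "fixed",
        "optimize"
      ],
      "title": "K Policy",
      "type": "string"
    },
    "k": {
      "default": 1.0,
      "title": "K",
      "type": "number"
    },
    "k_bounds": {
      "default": [
        0.5,
        2.0
      ],
      "maxItems": 2,
      "minItems": 2,
      "prefixItems": [
        {
          "type": "number"
        },
        {
          "type": "number"
        }
      ],
      "title": "K Bounds",
      "type": "array"
    },
    "k_region": {
      "anyOf": [
        {
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "K Region"
    },
    "segment_threshold": {
      "default": 0.05,
      "title": "Segment Threshold",
      "type": "number"
    },
    "segment_min_gap": {
      "default": 10.0,
      "title": "Segment Min Gap",
      "type": "number"
    },
    "regions": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/RegionConfig"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Regions"
    },
    "search": {
      "default": [
        -80.0,
        80.0
      ],
      "maxItems": 2,
      "minItems": 2,
      "prefixItems": [
        {
          "type": "number"
        },
        {
          "type": "number"
        }
      ],
      "title": "Search",
      "type": "array"
    },
    "resolution": {
      "default": 0.001,
      "title": "Resolution",
      "type": "number"
    },
    "reference_label": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Reference Label"
    },
    "ensemble_path": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ensemble Path"
    },
    "temperature": {
      "default": 298.15,
      "title": "Temperature",
      "type": "number"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "out_dir": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Out Dir"
    }
  },
  "title": "AnalysisConfig",
  "type": "object"
}
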