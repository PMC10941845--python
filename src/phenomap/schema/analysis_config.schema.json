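{
  "$defs": {
    "AnomalyParams": {
      "additionalProperties": false,
      "properties": {
        "family": {
          "default": "gaussian_mixture",
          "enum": [
            "gaussian",
            "gaussian_mixture"
          ],
          "title": "Family",
          "type": "string"
        },
        "k_min": {
          "default": 1,
          "title": "K Min",
          "type": "integer"
        },
        "k_max": {
          "default": 8,
          "title": "K Max",
          "type": "integer"
        },
        "whiten_dim": {
          "default": 32,
          "title": "Whiten Dim",
          "type": "integer"
        },
        "aggregation": {
          "default": "mean",
          "enum": [
            "mean",
            "median",
            "max"
          ],
          "title": "Aggregation",
          "type": "string"
        },
        "percentiles": {
          "default": [
            5.0,
            95.0
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
          "title": "Percentiles",
          "type": "array"
        }
      },
      "title": "AnomalyParams",
      "type": "object"
    },
    "ClusterParams": {
      "additionalProperties": false,
      "properties": {
        "methods": {
          "default": [
            "minibatch_kmeans",
            "gaussian_mixture"
          ],
          "items": {
            "type": "string"
          },
          "title": "Methods",
          "type": "array"
        },
        "k_min": {
          "default": 2,
          "title": "K Min",
          "type": "integer"
        },
        "k_max": {
          "default": 8,
          "title": "K Max",
          "type": "integer"
        },
        "pa_reps": {
          "default": 100,
          "title": "Pa Reps",
          "type": "integer"
        },
        "pa_percentile": {
          "default": 95.0,
          "title": "Pa Percentile",
          "type": "number"
        },
        "tsne_perplexity": {
          "default": 30.0,
          "title": "Tsne Perplexity",
          "type": "number"
        }
      },
      "title": "ClusterParams",
      "type": "object"
    },
    "CohortParams": {
      "additionalProperties": false,
      "properties": {
        "n_per_stage": {
          "default": 10,
          "title": "N Per Stage",
          "type": "integer"
        },
        "grid_shape": {
          "default": [
            64,
            64,
            48
          ],
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
          "title": "Grid Shape",
          "type": "array"
        },
        "n_sites": {
          "default": 4,
          "title": "N Sites",
          "type": "integer"
        },
        "site_sd": {
          "default": 3.0,
          "title": "Site Sd",
          "type": "number"
        }
      },
      "title": "CohortParams",
      "type": "object"
    },
    "FeatureParams": {
      "additionalProperties": false,
      "properties": {
        "featurizer": {
          "default": "histogram",
          "enum": [
            "histogram",
            "contrastive"
          ],
          "title": "Featurizer",
          "type": "string"
        },
        "feature_dim": {
          "default": 512,
          "title": "Feature Dim",
          "type": "integer"
        },
        "patch_size": {
          "default": 50,
          "title": "Patch Size",
          "type": "integer"
        },
        "overlap_fraction": {
          "default": 0.2,
          "title": "Overlap Fraction",
          "type": "number"
        },
        "min_lung_fraction": {
          "default": 0.2,
          "title": "Min Lung Fraction",
          "type": "number"
        }
      },
      "title": "FeatureParams",
      "type": "object"
    },
    "StatsParams": {
      "additionalProperties": false,
      "properties": {
        "n_boot": {
          "default": 10000,
          "title": "N Boot",
          "type": "integer"
        },
        "alpha": {
          "default": 0.05,
          "title": "Alpha",
          "type": "number"
        },
        "holm": {
          "default": true,
          "title": "Holm",
          "type": "boolean"
        }
      },
      "title": "StatsParams",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Full pipeline configuration; unknown keys are rejected.",
  "properties": {
    "out_dir": {
      "title": "Out Dir",
      "type": "string"
    },
    "cohort_dir": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Cohort Dir"
    },
    "run_simulate": {
      "default": true,
      "title": "Run Simulate",
      "type": "boolean"
    },
    "cohort": {
      "$ref": "#/$defs/CohortParams"
    },
    "features": {
      "$ref": "#/$defs/FeatureParams"
    },
    "anomaly": {
      "$ref": "#/$defs/AnomalyParams"
    },
    "cluster": {
      "$ref": "#/$defs/ClusterParams"
    },
    "stats": {
      "$ref": "#/$defs/StatsParams"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    }
  },
  "required": [
    "out_dir"
  ],
  "title": "AnalysisConfig",
  "type": "object"
}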