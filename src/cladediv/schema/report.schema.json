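{
  "$defs": {
    "CladeSummary": {
      "description": "Per-clade block of the report.",
      "properties": {
        "designation": {
          "title": "Designation",
          "type": "string"
        },
        "leaf_count": {
          "title": "Leaf Count",
          "type": "integer"
        },
        "mean_length": {
          "title": "Mean Length",
          "type": "number"
        },
        "median_length": {
          "title": "Median Length",
          "type": "number"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "pruned_leaf_count": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Pruned Leaf Count"
        },
        "representatives": {
          "anyOf": [
            {
              "additionalProperties": {
                "type": "string"
              },
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Representatives"
        },
        "sample_size": {
          "title": "Sample Size",
          "type": "integer"
        },
        "species_count": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Species Count"
        },
        "unmatched_leaves": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Unmatched Leaves"
        }
      },
      "required": [
        "name",
        "designation",
        "leaf_count",
        "sample_size",
        "mean_length",
        "median_length"
      ],
      "title": "CladeSummary",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "include_stem": {
          "default": false,
          "title": "Include Stem",
          "type": "boolean"
        },
        "input_sha256": {
          "default": "",
          "title": "Input Sha256",
          "type": "string"
        },
        "species_pattern": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Species Pattern"
        },
        "tool": {
          "default": "cladediv",
          "title": "Tool",
          "type": "string"
        },
        "unmatched_policy": {
          "default": "exclude",
          "title": "Unmatched Policy",
          "type": "string"
        },
        "version": {
          "default": "0.1.0",
          "title": "Version",
          "type": "string"
        }
      },
      "title": "Provenance",
      "type": "object"
    },
    "SpeciesSetBlock": {
      "description": "Venn-style species summary of the full (unpruned) clades.",
      "properties": {
        "common": {
          "title": "Common",
          "type": "integer"
        },
        "common_species": {
          "items": {
            "type": "string"
          },
          "title": "Common Species",
          "type": "array"
        },
        "relation": {
          "title": "Relation",
          "type": "string"
        },
        "unique_a": {
          "title": "Unique A",
          "type": "integer"
        },
        "unique_a_species": {
          "items": {
            "type": "string"
          },
          "title": "Unique A Species",
          "type": "array"
        },
        "unique_b": {
          "title": "Unique B",
          "type": "integer"
        },
        "unique_b_species": {
          "items": {
            "type": "string"
          },
          "title": "Unique B Species",
          "type": "array"
        }
      },
      "required": [
        "common",
        "unique_a",
        "unique_b",
        "relation",
        "common_species",
        "unique_a_species",
        "unique_b_species"
      ],
      "title": "SpeciesSetBlock",
      "type": "object"
    },
    "TestResult": {
      "description": "Outcome of one two-sample test.\n\nEither the statistic fields are populated, or ``error`` explains why the\ntest was not computable on these samples (e.g. zero variance); the other\ntests in a panel still run.",
      "properties": {
        "df": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Df"
        },
        "error": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Error"
        },
        "method": {
          "anyOf": [
            {
              "enum": [
                "exact",
                "normal_approx"
              ],
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Method"
        },
        "n1": {
          "title": "N1",
          "type": "integer"
        },
        "n2": {
          "title": "N2",
          "type": "integer"
        },
        "name": {
          "enum": [
            "student_t",
            "welch_t",
            "mann_whitney_u"
          ],
          "title": "Name",
          "type": "string"
        },
        "p_display": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Display"
        },
        "p_value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Value"
        },
        "statistic": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Statistic"
        }
      },
      "required": [
        "name",
        "n1",
        "n2"
      ],
      "title": "TestResult",
      "type": "object"
    }
  },
  "description": "Complete result of one clade-divergence analysis.\n\n``samples`` holds the two branch-length samples verbatim (plot-ready for\na boxplot); ``species_sets`` holds Venn counts when a pattern was given.",
  "properties": {
    "clade_a": {
      "$ref": "#/$defs/CladeSummary"
    },
    "clade_b": {
      "$ref": "#/$defs/CladeSummary"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "samples": {
      "additionalProperties": {
        "items": {
          "type": "number"
        },
        "type": "array"
      },
      "title": "Samples",
      "type": "object"
    },
    "species_sets": {
      "anyOf": [
        {
          "$ref": "#/$defs/SpeciesSetBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "tests": {
      "items": {
        "$ref": "#/$defs/TestResult"
      },
      "title": "Tests",
      "type": "array"
    }
  },
  "required": [
    "clade_a",
    "clade_b",
    "tests",
    "samples",
    "provenance"
  ],
  "title": "cladediv divergence report",
  "type": "object"
}
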