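{
  "title": "npdiv pipeline summary",
  "required": {
    "parameters": "object",
    "input": {
      "n_features_raw": "integer",
      "n_samples": "integer"
    },
    "preprocess": {
      "n_features": "integer",
      "n_isolates": "integer",
      "singleton_fraction": "number"
    },
    "partition": {
      "selected_k": "integer",
      "silhouette_by_k": "object",
      "permanova_clade": {
        "pseudo_F": "number",
        "p_value": "number"
      },
      "permanova_cluster": {
        "pseudo_F": "number",
        "p_value": "number"
      }
    },
    "diversity": {
      "richness_median_by_group": "object",
      "anova_F": "number",
      "anova_p": "number",
      "coverage_targets": "object",
      "end_slope_by_group": "object"
    },
    "scaffolds": "object",
    "venn_features": {
      "total": "integer",
      "core_count": "integer",
      "core_percent": "number",
      "unique_counts": "object",
      "shared_two_plus": "integer"
    },
    "ordered_accumulation": {
      "largest_first": "object",
      "smallest_first": "object"
    },
    "geography": "object"
  }
}
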