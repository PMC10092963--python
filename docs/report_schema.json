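{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hepaflow joint report",
  "type": "object",
  "required": ["software", "seed", "config", "densitometry", "dls"],
  "properties": {
    "software": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"const": "hepaflow"},
        "version": {"type": "string"}
      }
    },
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "densitometry": {
      "type": "object",
      "required": ["status"],
      "properties": {
        "status": {"enum": ["ok", "failed", "missing"]},
        "cause": {"type": "string"},
        "pdr_pct_per_min": {"type": "number"},
        "c1_mg_per_l": {"type": ["number", "null"]},
        "intercept_pct": {"type": "number"},
        "r_squared": {"type": "number", "minimum": 0, "maximum": 1},
        "residual_sd_pct": {"type": "number", "minimum": 0},
        "n_points": {"type": "integer", "minimum": 10},
        "n_excluded": {"type": "integer", "minimum": 0},
        "segmentation": {
          "type": "object",
          "required": ["baseline_window", "t0_min", "peak_time_min", "t1_min", "elimination_window", "u0_v"],
          "properties": {
            "baseline_window": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2},
            "t0_min": {"type": "number"},
            "peak_time_min": {"type": "number"},
            "t1_min": {"type": "number"},
            "elimination_window": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2},
            "u0_v": {"type": "number", "exclusiveMinimum": 0}
          }
        }
      }
    },
    "dls": {
      "type": "object",
      "required": ["status"],
      "properties": {
        "status": {"enum": ["ok", "failed", "missing"]},
        "cause": {"type": "string"},
        "mean_velocity_mm_per_s": {"type": "number", "exclusiveMinimum": 0},
        "sd_velocity_mm_per_s": {"type": "number", "minimum": 0},
        "n_replicates": {"type": "integer", "minimum": 1},
        "n_failed": {"type": "integer", "minimum": 0},
        "velocities_mm_per_s": {"type": "array", "items": {"type": "number"}},
        "tau_c_s": {"type": "array", "items": {"type": "number"}}
      }
    }
  }
}
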