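{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "popkin session log, schema_version 1",
  "description": "One participant's bubble-popping game session. Coordinates are millimetres, origin top-left, x rightward, y downward; times are seconds since the analysis window started. A bubble's trajectory is y(t) = y0_mm - speed_mm_s * (t - spawn_t) over [spawn_t, end_t].",
  "type": "object",
  "required": ["schema_version", "session_id", "group", "age_months", "config",
               "touches", "accel", "bubbles", "pops"],
  "properties": {
    "schema_version": {"const": 1},
    "session_id": {"type": "string"},
    "group": {"type": "string", "description": "e.g. NT | autistic | autistic_adhd"},
    "age_months": {"type": "number"},
    "iq": {"type": ["number", "null"]},
    "clinical_scores": {"type": "object", "additionalProperties": {"type": "number"}},
    "config": {
      "type": "object",
      "required": ["screen_width_mm", "screen_height_mm", "n_lanes",
                   "pop_radius_mm", "bubble_radius_mm", "bubble_speed_mm_s",
                   "spawn_gap_s", "session_duration_s", "sensor_rate_hz",
                   "targeting_radius_mm", "accuracy_decay_mm",
                   "exploration_cell_mm", "double_touch_window_s",
                   "double_touch_radius_mm", "min_touches_qc"],
      "additionalProperties": {"type": "number"}
    },
    "touches": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["touch_id", "samples"],
        "properties": {
          "touch_id": {"type": "string"},
          "samples": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "array",
              "prefixItems": [{"type": "number"}, {"type": "number"},
                              {"type": "number"}],
              "minItems": 3, "maxItems": 3,
              "description": "[t, x_mm, y_mm], strictly increasing t"
            }
          }
        }
      }
    },
    "accel": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "number"}, {"type": "number"},
                        {"type": "number"}, {"type": "number"}],
        "minItems": 4, "maxItems": 4,
        "description": "[t, ax, ay, az] in m/s^2, non-decreasing t"
      }
    },
    "bubbles": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["bubble_id", "lane", "character_id", "spawn_t",
                     "center_x_mm", "y0_mm", "speed_mm_s", "end_t",
                     "end_reason"],
        "properties": {
          "bubble_id": {"type": "string"},
          "lane": {"type": "integer", "minimum": 0},
          "character_id": {"type": "integer"},
          "spawn_t": {"type": "number"},
          "center_x_mm": {"type": "number"},
          "y0_mm": {"type": "number"},
          "speed_mm_s": {"type": "number", "exclusiveMinimum": 0},
          "end_t": {"type": "number"},
          "end_reason": {"enum": ["popped", "exited"]}
        }
      }
    },
    "pops": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["t", "bubble_id", "touch_id", "distance_to_center_mm"],
        "properties": {
          "t": {"type": "number"},
          "bubble_id": {"type": "string"},
          "touch_id": {"type": "string"},
          "distance_to_center_mm": {"type": "number", "maximum": 18.5}
        }
      }
    },
    "meta": {"type": "object"}
  }
}
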