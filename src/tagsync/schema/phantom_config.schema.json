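{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "tagsync/phantom_config/v1",
  "title": "PhantomConfig",
  "description": "Generative description of one synthetic tagged-CMR subject. Angles in degrees (clockwise from the apex, 0 deg at the anterior RV-LV junction); lengths in mm; times in ms.",
  "type": "object",
  "properties": {
    "grid_size": {"type": "integer", "minimum": 16},
    "pixel_spacing": {"type": "number", "exclusiveMinimum": 0},
    "n_slices": {"type": "integer", "minimum": 1},
    "slice_thickness": {"type": "number", "exclusiveMinimum": 0},
    "slice_gap": {"type": "number", "minimum": 0},
    "endo_radius": {"type": "number", "exclusiveMinimum": 0},
    "epi_radius": {"type": "number", "exclusiveMinimum": 0},
    "n_frames": {"type": "integer", "minimum": 2},
    "frame_interval": {"type": "number", "exclusiveMinimum": 0},
    "avc_frame": {"type": "integer", "minimum": 0},
    "tag_spacing": {"type": "number", "exclusiveMinimum": 0},
    "tag_directions": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}}
    },
    "sector_amplitudes": {"type": "array", "minItems": 6, "maxItems": 6, "items": {"type": "number", "minimum": 0}},
    "sector_delays": {"type": "array", "minItems": 6, "maxItems": 6, "items": {"type": "number"}},
    "post_systolic_fraction": {"type": "number", "minimum": 0, "maximum": 1},
    "post_systolic_lag": {"type": "number", "minimum": 0},
    "edema_arc": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}},
    "necrosis_arc": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}},
    "signal_levels": {
      "type": "object",
      "properties": {
        "remote_mean": {"type": "number"},
        "remote_sd": {"type": "number", "minimum": 0},
        "edema_mean": {"type": "number"},
        "necrosis_mean": {"type": "number"}
      },
      "additionalProperties": false
    },
    "noise_sd": {"type": "number", "minimum": 0},
    "tag_fading": {"type": "number", "minimum": 0},
    "seed": {"type": "integer", "minimum": 0}
  },
  "additionalProperties": false
}
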