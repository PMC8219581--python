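{
  "schema_version": "1",
  "name": "tutorial",
  "settings": {
    "display": {
      "model_name": "iPad (6th generation, 2018)",
      "width_px": 2048,
      "height_px": 1536,
      "pixels_per_cm": 103.94,
      "refresh_rate": 60.0,
      "max_luminance": 500.0,
      "viewing_distance": 40.0
    },
    "audio_rate": 44100,
    "av_offset_ms": 0.0,
    "rng_seed": 0
  },
  "stimuli": [
    {
      "name": "stimulus1",
      "type": "patch",
      "shape": "cross",
      "properties": {
        "size_x": {"value": 100, "unit": "px"},
        "size_y": {"value": 100, "unit": "px"},
        "color": [0.0, 0.0, 0.0]
      }
    },
    {
      "name": "stimulus2",
      "type": "grating",
      "shape": "ellipse",
      "properties": {
        "size_x": {"value": 300, "unit": "px"},
        "size_y": {"value": 300, "unit": "px"},
        "spatial_frequency": {"value": 2.0, "unit": "cpd"},
        "contrast": 0.8,
        "phase": 0.0,
        "gratingRotation": {"mode": "variable"}
      }
    }
  ],
  "sections": [
    {
      "name": "section1",
      "repetitions": 20,
      "next_section": "END",
      "scenes": [
        {
          "name": "scene1",
          "duration": {"value": 0.5, "unit": "s"},
          "objects": ["stimulus1"]
        },
        {
          "name": "scene2",
          "duration": {"value": 1.0, "unit": "s"},
          "objects": ["stimulus2"],
          "response": {
            "kind": "left_or_right",
            "values": {"left": -1, "right": 1}
          }
        }
      ],
      "variables": [
        {
          "target": "scene2_object1_gratingRotation",
          "list": "list1",
          "selection_method": "all_values_random_order"
        }
      ]
    }
  ],
  "lists": [
    {
      "name": "list1",
      "values": [-0.03, -0.02, -0.01, 0.0, 0.01, 0.02, 0.03]
    }
  ],
  "first_section": "section1"
}
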