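{
  "ipad-6th-gen": {
    "model_name": "iPad (6th generation, 2018)",
    "width_px": 2048,
    "height_px": 1536,
    "pixels_per_cm": 103.94,
    "refresh_rate": 60.0,
    "max_luminance": 500.0,
    "viewing_distance": 40.0
  },
  "iphone-x": {
    "model_name": "iPhone X (2017)",
    "width_px": 2436,
    "height_px": 1125,
    "pixels_per_cm": 180.31,
    "refresh_rate": 60.0,
    "max_luminance": 625.0,
    "viewing_distance": 35.0
  },
  "ipad-pro-10.5": {
    "model_name": "iPad Pro 10.5-inch (2017)",
    "width_px": 2224,
    "height_px": 1668,
    "pixels_per_cm": 103.94,
    "refresh_rate": 120.0,
    "max_luminance": 600.0,
    "viewing_distance": 40.0
  },
  "generic-monitor": {
    "model_name": "Generic 24-inch 1080p monitor",
    "width_px": 1920,
    "height_px": 1080,
    "pixels_per_cm": 36.27,
    "refresh_rate": 60.0,
    "max_luminance": 250.0,
    "viewing_distance": 57.0
  }
}
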