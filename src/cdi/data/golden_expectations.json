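{
  "nordic-snow": {
    "v4": {
      "no_drought": 2532,
      "watch": 308,
      "warning": 262,
      "alert": 216,
      "recovery": 219,
      "temp_sm_recovery": 41,
      "temp_veg_recovery": 22,
      "missing": 0
    }
  },
  "france-offseason": {
    "v4": {
      "no_drought": 1844,
      "watch": 303,
      "warning": 702,
      "alert": 419,
      "recovery": 240,
      "temp_sm_recovery": 46,
      "temp_veg_recovery": 46,
      "missing": 0
    },
    "v2": {
      "no_drought": 1778,
      "watch": 263,
      "warning": 600,
      "alert": 607,
      "recovery": 242,
      "temp_sm_recovery": 42,
      "temp_veg_recovery": 68,
      "missing": 0
    }
  },
  "all-zero": {
    "v4": {
      "no_drought": 0,
      "watch": 0,
      "warning": 0,
      "alert": 0,
      "recovery": 0,
      "temp_sm_recovery": 0,
      "temp_veg_recovery": 0,
      "missing": 1296
    }
  }
}
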