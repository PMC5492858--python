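{
  "family": "Zynq-7000",
  "devices": {
    "XC7Z010": {"lut": 17600, "ff": 35200, "bram_blocks": 60, "dsp": 80},
    "XC7Z015": {"lut": 46200, "ff": 92400, "bram_blocks": 95, "dsp": 160},
    "XC7Z020": {"lut": 53200, "ff": 106400, "bram_blocks": 140, "dsp": 220},
    "XC7Z030": {"lut": 78600, "ff": 157200, "bram_blocks": 265, "dsp": 400},
    "XC7Z035": {"lut": 171900, "ff": 343800, "bram_blocks": 500, "dsp": 900},
    "XC7Z045": {"lut": 218600, "ff": 437200, "bram_blocks": 545, "dsp": 900},
    "XC7Z100": {"lut": 277400, "ff": 554800, "bram_blocks": 755, "dsp": 2020}
  },
  "feature_ip": {
    "note": "Per-component figures come from separate place-and-route runs; the packaged-IP TOTAL is the figure used for device fit and does not equal the column sums.",
    "components": {
      "fifos_2x_depth_2048": {"cycles": null, "dsp": 0, "bram_blocks": 4, "lut": 218, "ff": 0},
      "fft_fsm": {"cycles": 28713, "dsp": 23, "bram_blocks": 7, "lut": 1551, "ff": 1933},
      "ram": {"cycles": null, "dsp": 0, "bram_blocks": 1, "lut": 0, "ff": 0},
      "rom": {"cycles": null, "dsp": 0, "bram_blocks": 64, "lut": 32, "ff": 1},
      "mfcc_fsm": {"cycles": 49156, "dsp": 2, "bram_blocks": 0, "lut": 773, "ff": 1263},
      "log": {"cycles": null, "dsp": 4, "bram_blocks": 0, "lut": 710, "ff": 1192},
      "dct_fsm": {"cycles": 53, "dsp": 2, "bram_blocks": 1, "lut": 1254, "ff": 2987}
    },
    "total": {"dsp": 31, "bram_blocks": 73, "lut": 4489, "ff": 7677},
    "critical_path_cycles": 49156,
    "clock_hz": 100000000
  }
}
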