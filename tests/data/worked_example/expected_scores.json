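{
 "bin_size": 7,
 "dpa": {
  "D1": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "D2": {
   "PWY1": 0.0,
   "PWY2": 0.3322103421668191,
   "PWY3": 0.0
  },
  "D3": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "D4": {
   "PWY1": 0.0,
   "PWY2": 0.16610517108340955,
   "PWY3": 0.0
  },
  "D5": {
   "PWY1": 0.0,
   "PWY2": 0.3322103421668191,
   "PWY3": 0.0
  },
  "D6": {
   "PWY1": 0.0,
   "PWY2": 0.19932620530009146,
   "PWY3": 0.0
  }
 },
 "gini": {
  "D1": null,
  "D2": 0.0,
  "D3": null,
  "D4": 0.0,
  "D5": 0.0,
  "D6": 0.0
 },
 "ppa": {
  "P3": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "P4": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "P5": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "P6": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "P7": {
   "PWY1": 0.0,
   "PWY2": 0.9966310265004573,
   "PWY3": 0.0
  },
  "P8": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  }
 },
 "ps": {
  "D1": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "D2": {
   "PWY1": 0.0,
   "PWY2": 0.3322103421668191,
   "PWY3": 0.0
  },
  "D3": {
   "PWY1": 0.0,
   "PWY2": 0.0,
   "PWY3": 0.0
  },
  "D4": {
   "PWY1": 0.0,
   "PWY2": 0.16610517108340955,
   "PWY3": 0.0
  },
  "D5": {
   "PWY1": 0.0,
   "PWY2": 0.3322103421668191,
   "PWY3": 0.0
  },
  "D6": {
   "PWY1": 0.0,
   "PWY2": 0.19932620530009146,
   "PWY3": 0.0
  }
 }
}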