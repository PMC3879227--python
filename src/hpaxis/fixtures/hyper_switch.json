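{
 "name": "hyper_switch",
 "params": {
  "V_in": 1.0,
  "V_ex": 1.0,
  "V_nu": 1.0,
  "kdiff1": 0.15,
  "k1ex": 13.8,
  "k2in": 3.5,
  "k2ex": 0.0081,
  "k3in": 0.885,
  "k3ex": 1.26,
  "d1": 0.0083,
  "d2": 0.038,
  "d3": 1.0799999999999998,
  "d4": 0.0093,
  "d5": 0.9750000000000001,
  "d6": 0.074,
  "d7": 0.038,
  "d8": 0.0085,
  "d9": 0.095,
  "d10": 0.9450000000000001,
  "d11": 0.042,
  "d12": 0.72,
  "d13": 0.615,
  "d14": 0.96,
  "d15": 0.051,
  "kGRC": 0.2,
  "kGRdim": 0.38,
  "kCRC": 4.7,
  "kGC2": 100.0,
  "K1": 1.6,
  "K3": 22.0,
  "K4": 16.0,
  "K5": 4.0,
  "K6": 0.072,
  "K7": 0.9,
  "K8": 0.012,
  "K9": 0.76,
  "v1": 0.84,
  "v2": 0.048,
  "v3": 0.05,
  "v4": 5.55,
  "v5": 0.00525,
  "v6": 57.0,
  "v7": 0.026,
  "v8": 0.00092,
  "ks": 0.84,
  "ksb": 0.0087,
  "ktl1": 5.1000000000000005,
  "ktl2": 0.71,
  "ktrs1": 7.05,
  "ktrs2": 0.38,
  "h": 2.0,
  "stress_basal": 0.1
 },
 "seed": 1,
 "n_starts": 24,
 "note": "synthetic regime; this package's own choice, not a literature value",
 "target_kind": "fold_bistable_hyper",
 "verification": {
  "n_lp": 2,
  "n_hopf": 0,
  "kind": "irreversible_bistable",
  "orientation": "hyper",
  "S1": 0.56319,
  "S2": 0.067155
 }
}
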