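{
 "name": "hypo_switch",
 "params": {
  "V_in": 1.0,
  "V_ex": 1.0,
  "V_nu": 1.0,
  "kdiff1": 0.092,
  "k1ex": 0.45,
  "k2in": 0.012,
  "k2ex": 0.0039,
  "k3in": 0.1,
  "k3ex": 0.05,
  "d1": 0.0062,
  "d2": 0.12,
  "d3": 0.013,
  "d4": 0.011,
  "d5": 0.023,
  "d6": 0.05,
  "d7": 0.05,
  "d8": 0.29,
  "d9": 0.015,
  "d10": 0.05,
  "d11": 0.012,
  "d12": 0.05,
  "d13": 0.05,
  "d14": 0.05,
  "d15": 0.081,
  "kGRC": 5.8,
  "kGRdim": 17.0,
  "kCRC": 10.0,
  "kGC2": 100.0,
  "K1": 4.7,
  "K3": 46.0,
  "K4": 4.4,
  "K5": 1.0,
  "K6": 2.5,
  "K7": 0.52,
  "K8": 2.1,
  "K9": 5.9,
  "v1": 0.12,
  "v2": 0.05,
  "v3": 0.05,
  "v4": 0.065,
  "v5": 0.0099,
  "v6": 0.093,
  "v7": 0.0044,
  "v8": 1.7,
  "ks": 2.6,
  "ksb": 0.01,
  "ktl1": 0.7,
  "ktl2": 0.44,
  "ktrs1": 0.5,
  "ktrs2": 0.15,
  "h": 2.0,
  "stress_basal": 0.1
 },
 "seed": 1,
 "n_starts": 24,
 "note": "synthetic regime; this package's own choice, not a literature value",
 "target_kind": "fold_bistable_hypo",
 "verification": {
  "n_lp": 2,
  "n_hopf": 0,
  "kind": "irreversible_bistable",
  "orientation": "hypo",
  "S1": 0.468912,
  "S2": 0.023077
 }
}
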