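{
 "name": "oscillatory",
 "params": {
  "V_in": 1.0,
  "V_ex": 1.0,
  "V_nu": 1.0,
  "kdiff1": 0.089,
  "k1ex": 1.0,
  "k2in": 1.9,
  "k2ex": 0.019,
  "k3in": 0.1,
  "k3ex": 0.05,
  "d1": 0.01,
  "d2": 0.076,
  "d3": 0.043,
  "d4": 0.011,
  "d5": 0.056,
  "d6": 0.05,
  "d7": 0.05,
  "d8": 0.018,
  "d9": 0.12,
  "d10": 0.05,
  "d11": 0.01,
  "d12": 0.05,
  "d13": 0.05,
  "d14": 0.05,
  "d15": 0.01,
  "kGRC": 0.49,
  "kGRdim": 0.38,
  "kCRC": 10.0,
  "kGC2": 100.0,
  "K1": 1.6,
  "K3": 8.2,
  "K4": 17.0,
  "K5": 1.0,
  "K6": 0.13,
  "K7": 0.84,
  "K8": 0.018,
  "K9": 1.0,
  "v1": 0.91,
  "v2": 0.05,
  "v3": 0.05,
  "v4": 0.26,
  "v5": 0.00049,
  "v6": 3.0,
  "v7": 0.0034,
  "v8": 0.00018,
  "ks": 0.52,
  "ksb": 0.01,
  "ktl1": 0.38,
  "ktl2": 0.89,
  "ktrs1": 0.5,
  "ktrs2": 0.1,
  "h": 2.0,
  "stress_basal": 0.1
 },
 "seed": 1,
 "n_starts": 24,
 "note": "synthetic regime; this package's own choice, not a literature value",
 "target_kind": "hopf_oscillatory",
 "verification": {
  "n_lp": 2,
  "n_hopf": 2,
  "kind": "reversible_bistable",
  "orientation": "hyper",
  "S1": 0.319528,
  "S2": 0.29552,
  "period_min": 185.7,
  "phase_order": [
   "CRH",
   "ACTH_ex",
   "COR_ex"
  ]
 }
}
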