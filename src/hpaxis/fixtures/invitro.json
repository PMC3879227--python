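{
 "name": "invitro",
 "params": {
  "V_in": 1.0,
  "V_ex": 1.0,
  "V_nu": 1.0,
  "kdiff1": 0.013,
  "k1ex": 2.9,
  "k2in": 0.034,
  "k2ex": 0.016,
  "k3in": 0.1,
  "k3ex": 0.05,
  "d1": 0.13,
  "d2": 0.022,
  "d3": 0.0077,
  "d4": 0.092,
  "d5": 0.017,
  "d6": 0.05,
  "d7": 0.05,
  "d8": 0.02,
  "d9": 0.015,
  "d10": 0.033,
  "d11": 0.05,
  "d12": 0.05,
  "d13": 0.05,
  "d14": 0.05,
  "d15": 0.05,
  "kGRC": 1.1,
  "kGRdim": 3.0,
  "kCRC": 21.0,
  "kGC2": 980.0,
  "K1": 10.0,
  "K3": 10.0,
  "K4": 20.0,
  "K5": 0.58,
  "K6": 0.6,
  "K7": 1.5,
  "K8": 0.085,
  "K9": 1.0,
  "v1": 1.0,
  "v2": 0.05,
  "v3": 0.05,
  "v4": 0.093,
  "v5": 0.0019,
  "v6": 0.27,
  "v7": 0.01,
  "v8": 0.1,
  "ks": 1.0,
  "ksb": 0.01,
  "ktl1": 0.31,
  "ktl2": 0.5,
  "ktrs1": 0.35,
  "ktrs2": 0.5,
  "h": 2.0,
  "stress_basal": 0.1
 },
 "seed": 1,
 "n_starts": 24,
 "note": "synthetic in-vitro regime tuned to show the three qualitative protocol features (early A-rise, delayed B-burst, reduced B at 60 min); not a data reproduction"
}
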