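{
  "intercept": 0.793,
  "coefficients": {
    "cg03749154": -0.526,
    "cg16051114": -0.0269,
    "cg04144714": null,
    "cg20395773": 0.263,
    "cg17484237": -0.00086,
    "cg15006881": -0.012,
    "cg24644201": 1.058,
    "cg13038847": -0.0603
  },
  "lambda": null,
  "cv_mse": 0.0042,
  "meta": {
    "source": "published 8-CpG objective-response-rate model (pan-cancer, 18 TCGA cancer types)",
    "note": "The printed coefficient for cg04144714 is illegible in the source equation; it is stored as null and resolved at load time (default 0.0, overridable)."
  }
}
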