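{
 "derivation": {
  "n": 1072,
  "n_excluded": 603,
  "tp": 41,
  "fp": 428,
  "tn": 603,
  "fn": 0,
  "published": {
   "sensitivity": {
    "pct": 100,
    "ci": [
     0.91,
     1.0
    ]
   },
   "specificity": {
    "pct": 59,
    "ci": [
     0.56,
     0.62
    ],
    "anomalous": true,
    "note": "603/1031 = 58.5% renders as 58%; published 59% with an interval matching Wilson applied to p=0.59"
   },
   "ppv": {
    "pct": 9,
    "ci": [
     0.07,
     0.12
    ]
   },
   "npv": {
    "pct": 100,
    "ci": [
     0.99,
     1.0
    ]
   },
   "predicted_negative": {
    "pct": 56
   }
  }
 },
 "validation": {
  "n": 357,
  "n_excluded": 185,
  "tp": 6,
  "fp": 166,
  "tn": 185,
  "fn": 0,
  "published": {
   "sensitivity": {
    "pct": 100,
    "ci": [
     0.61,
     1.0
    ]
   },
   "specificity": {
    "pct": 53,
    "ci": [
     0.48,
     0.58
    ],
    "anomalous": true,
    "note": "exact-count Wilson lower bound is 0.47; published 0.48 matches Wilson applied to the rounded p=0.53"
   },
   "ppv": {
    "pct": 4,
    "ci": [
     0.02,
     0.07
    ],
    "anomalous": true,
    "note": "6/172 = 3.5% renders as 3%; published 4%. The interval matches exact-count Wilson"
   },
   "npv": {
    "pct": 100,
    "ci": [
     0.98,
     1.0
    ]
   },
   "predicted_negative": {
    "pct": 52,
    "ci": [
     0.47,
     0.57
    ]
   }
  }
 },
 "stroke_code": {
  "n": 81,
  "n_excluded": 35,
  "tp": 12,
  "fp": 34,
  "tn": 35,
  "fn": 0,
  "published": {
   "sensitivity": {
    "pct": 100,
    "ci": [
     0.76,
     1.0
    ]
   },
   "specificity": {
    "pct": 51,
    "ci": [
     0.39,
     0.62
    ]
   },
   "ppv": {
    "pct": 26,
    "ci": [
     0.16,
     0.4
    ]
   },
   "npv": {
    "pct": 100,
    "ci": [
     0.9,
     1.0
    ]
   },
   "predicted_negative": {
    "pct": 43,
    "ci": [
     0.33,
     0.54
    ]
   }
  }
 }
}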