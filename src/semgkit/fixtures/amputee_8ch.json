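{
  "channel_names": [
    "BR",
    "FCR",
    "ECR",
    "ED",
    "ECU",
    "FDP",
    "FDS",
    "FCU"
  ],
  "postures": [
    "rest",
    "spread",
    "finger pointing",
    "scissor sign",
    "V sign",
    "O.K. sign",
    "thumb up (hook)",
    "cylindrical grasp",
    "spherical grasp",
    "lateral pinch",
    "palmar pinch",
    "tip pinch"
  ],
  "amplitude_matrix": [
    [
      0.05,
      0.05,
      0.05,
      0.05,
      0.05,
      0.0425,
      0.05,
      0.05
    ],
    [
      0.2,
      0.1,
      0.55,
      0.85,
      0.6,
      0.1275,
      0.15,
      0.1
    ],
    [
      0.2,
      0.15,
      0.4,
      0.75,
      0.35,
      0.3825,
      0.45,
      0.2
    ],
    [
      0.25,
      0.2,
      0.3,
      0.6,
      0.45,
      0.4675,
      0.55,
      0.25
    ],
    [
      0.2,
      0.15,
      0.45,
      0.7,
      0.4,
      0.425,
      0.5,
      0.15
    ],
    [
      0.3,
      0.35,
      0.35,
      0.4,
      0.25,
      0.51,
      0.6,
      0.2
    ],
    [
      0.45,
      0.25,
      0.5,
      0.35,
      0.3,
      0.4675,
      0.55,
      0.35
    ],
    [
      0.55,
      0.55,
      0.4,
      0.45,
      0.45,
      0.68,
      0.8,
      0.5
    ],
    [
      0.5,
      0.5,
      0.45,
      0.5,
      0.5,
      0.6375,
      0.75,
      0.45
    ],
    [
      0.35,
      0.45,
      0.3,
      0.3,
      0.4,
      0.5525,
      0.65,
      0.55
    ],
    [
      0.3,
      0.4,
      0.35,
      0.35,
      0.3,
      0.51,
      0.6,
      0.3
    ],
    [
      0.28,
      0.36,
      0.38,
      0.38,
      0.33,
      0.49299999999999994,
      0.58,
      0.28
    ]
  ],
  "spectral_centroid_matrix": [
    [
      80.75,
      72.25,
      97.75,
      102.0,
      106.25,
      72.675,
      76.5,
      68.0
    ],
    [
      83.34090909090908,
      74.56818181818181,
      100.88636363636363,
      105.27272727272727,
      109.6590909090909,
      75.00681818181818,
      78.95454545454545,
      70.18181818181817
    ],
    [
      85.93181818181819,
      76.88636363636364,
      104.02272727272727,
      108.54545454545455,
      113.06818181818181,
      77.33863636363635,
      81.4090909090909,
      72.36363636363636
    ],
    [
      88.52272727272727,
      79.20454545454545,
      107.1590909090909,
      111.81818181818181,
      116.47727272727272,
      79.67045454545453,
      83.86363636363636,
      74.54545454545455
    ],
    [
      91.11363636363636,
      81.52272727272727,
      110.29545454545453,
      115.09090909090908,
      119.88636363636363,
      82.00227272727273,
      86.31818181818181,
      76.72727272727272
    ],
    [
      93.70454545454545,
      83.8409090909091,
      113.43181818181817,
      118.36363636363636,
      123.29545454545455,
      84.3340909090909,
      88.77272727272727,
      78.9090909090909
    ],
    [
      96.29545454545455,
      86.1590909090909,
      116.56818181818183,
      121.63636363636364,
      126.70454545454545,
      86.6659090909091,
      91.22727272727273,
      81.0909090909091
    ],
    [
      88.99772727272726,
      79.62954545454545,
      107.7340909090909,
      112.41818181818181,
      117.10227272727272,
      80.09795454545454,
      84.31363636363636,
      74.94545454545454
    ],
    [
      111.625,
      99.87500000000001,
      135.125,
      141.00000000000003,
      146.875,
      100.46249999999999,
      105.75,
      94.0
    ],
    [
      104.06818181818181,
      93.11363636363636,
      125.97727272727273,
      131.45454545454547,
      136.9318181818182,
      93.66136363636363,
      98.5909090909091,
      87.63636363636364
    ],
    [
      95.99318181818181,
      85.88863636363635,
      116.20227272727271,
      121.25454545454545,
      126.30681818181816,
      86.39386363636363,
      90.94090909090909,
      80.83636363636363
    ],
    [
      120.175,
      107.52499999999999,
      145.47500000000002,
      151.8,
      158.125,
      108.15749999999998,
      113.85,
      101.2
    ]
  ],
  "sigma_trial": [
    0.7,
    0.5,
    0.35,
    0.2,
    0.1
  ],
  "crosstalk_lambda": 0.1,
  "rest_amplitude": 0.05,
  "fs": 1926.0,
  "trial_s": 5.0,
  "sessions_per_day": 10,
  "seed": 0,
  "subject_id": "synthetic-amputee"
}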