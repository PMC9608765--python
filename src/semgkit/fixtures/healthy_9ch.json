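{
  "channel_names": [
    "FDS",
    "ED",
    "EDM",
    "EP",
    "FCR",
    "FCU",
    "ECR",
    "ECU",
    "BR"
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
      0.05,
      0.05,
      0.05,
      0.05
    ],
    [
      0.15,
      0.85,
      0.8,
      0.55,
      0.1,
      0.1,
      0.55,
      0.6,
      0.2
    ],
    [
      0.45,
      0.75,
      0.3,
      0.25,
      0.15,
      0.2,
      0.4,
      0.35,
      0.2
    ],
    [
      0.55,
      0.6,
      0.55,
      0.3,
      0.2,
      0.25,
      0.3,
      0.45,
      0.25
    ],
    [
      0.5,
      0.7,
      0.65,
      0.35,
      0.15,
      0.15,
      0.45,
      0.4,
      0.2
    ],
    [
      0.6,
      0.4,
      0.25,
      0.6,
      0.35,
      0.2,
      0.35,
      0.25,
      0.3
    ],
    [
      0.55,
      0.35,
      0.3,
      0.7,
      0.25,
      0.35,
      0.5,
      0.3,
      0.45
    ],
    [
      0.8,
      0.45,
      0.3,
      0.35,
      0.55,
      0.5,
      0.4,
      0.45,
      0.55
    ],
    [
      0.75,
      0.5,
      0.35,
      0.4,
      0.5,
      0.45,
      0.45,
      0.5,
      0.5
    ],
    [
      0.65,
      0.3,
      0.2,
      0.5,
      0.45,
      0.55,
      0.3,
      0.4,
      0.35
    ],
    [
      0.6,
      0.35,
      0.25,
      0.45,
      0.4,
      0.3,
      0.35,
      0.3,
      0.3
    ],
    [
      0.58,
      0.38,
      0.28,
      0.48,
      0.36,
      0.28,
      0.38,
      0.33,
      0.28
    ]
  ],
  "spectral_centroid_matrix": [
    [
      76.5,
      102.0,
      110.5,
      93.5,
      72.25,
      68.0,
      97.75,
      106.25,
      80.75
    ],
    [
      78.95454545454545,
      105.27272727272727,
      114.04545454545453,
      96.49999999999999,
      74.56818181818181,
      70.18181818181817,
      100.88636363636363,
      109.6590909090909,
      83.34090909090908
    ],
    [
      81.4090909090909,
      108.54545454545455,
      117.5909090909091,
      99.5,
      76.88636363636364,
      72.36363636363636,
      104.02272727272727,
      113.06818181818181,
      85.93181818181819
    ],
    [
      83.86363636363636,
      111.81818181818181,
      121.13636363636363,
      102.5,
      79.20454545454545,
      74.54545454545455,
      107.1590909090909,
      116.47727272727272,
      88.52272727272727
    ],
    [
      86.31818181818181,
      115.09090909090908,
      124.68181818181817,
      105.49999999999999,
      81.52272727272727,
      76.72727272727272,
      110.29545454545453,
      119.88636363636363,
      91.11363636363636
    ],
    [
      88.77272727272727,
      118.36363636363636,
      128.22727272727272,
      108.5,
      83.8409090909091,
      78.9090909090909,
      113.43181818181817,
      123.29545454545455,
      93.70454545454545
    ],
    [
      91.22727272727273,
      121.63636363636364,
      131.77272727272728,
      111.5,
      86.1590909090909,
      81.0909090909091,
      116.56818181818183,
      126.70454545454545,
      96.29545454545455
    ],
    [
      84.31363636363636,
      112.41818181818181,
      121.78636363636363,
      103.04999999999998,
      79.62954545454545,
      74.94545454545454,
      107.7340909090909,
      117.10227272727272,
      88.99772727272726
    ],
    [
      105.75,
      141.00000000000003,
      152.75,
      129.25,
      99.87500000000001,
      94.0,
      135.125,
      146.875,
      111.625
    ],
    [
      98.5909090909091,
      131.45454545454547,
      142.4090909090909,
      120.5,
      93.11363636363636,
      87.63636363636364,
      125.97727272727273,
      136.9318181818182,
      104.06818181818181
    ],
    [
      90.94090909090909,
      121.25454545454545,
      131.3590909090909,
      111.14999999999999,
      85.88863636363635,
      80.83636363636363,
      116.20227272727271,
      126.30681818181816,
      95.99318181818181
    ],
    [
      113.85,
      151.8,
      164.45000000000002,
      139.15,
      107.52499999999999,
      101.2,
      145.47500000000002,
      158.125,
      120.175
    ]
  ],
  "sigma_trial": [
    0.5,
    0.25,
    0.1
  ],
  "crosstalk_lambda": 0.1,
  "rest_amplitude": 0.05,
  "fs": 1926.0,
  "trial_s": 5.0,
  "sessions_per_day": 10,
  "seed": 0,
  "subject_id": "synthetic"
}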