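{
 "transition_matrix": [
  [
   0.7872,
   0.1702,
   0.0425,
   0
  ],
  [
   0.3103,
   0.5172,
   0.1724,
   0
  ],
  [
   0.0353,
   0.0706,
   0.8353,
   0.0588
  ],
  [
   0,
   0,
   0.2631,
   0.7368
  ]
 ],
 "spatial_transition_matrices": {
  "1": [
   [
    0.9091,
    0.0909,
    0,
    0
   ],
   [
    0.4,
    0.6,
    0,
    0
   ],
   [
    0,
    1,
    0,
    0
   ],
   [
    0,
    0,
    0,
    1
   ]
  ],
  "2": [
   [
    0.8667,
    0.1333,
    0,
    0
   ],
   [
    0.2222,
    0.5556,
    0.2222,
    0
   ],
   [
    0.0417,
    0.0833,
    0.8333,
    0.0417
   ],
   [
    0,
    0,
    0.3333,
    0.6667
   ]
  ],
  "3": [
   [
    0.7059,
    0.2353,
    0.0589,
    0
   ],
   [
    0.375,
    0.625,
    0,
    0
   ],
   [
    0,
    0.0294,
    0.8824,
    0.0882
   ],
   [
    0,
    0,
    0.8,
    0.2
   ]
  ],
  "4": [
   [
    0.5,
    0.25,
    0.25,
    0
   ],
   [
    0.2857,
    0.2857,
    0.4286,
    0
   ],
   [
    0.08,
    0.08,
    0.8,
    0.04
   ],
   [
    0,
    0,
    0,
    1
   ]
  ]
 },
 "initial_distribution": [
  0.26,
  0.16,
  0.47,
  0.11
 ],
 "limiting_distributions": {
  "no_lag": [
   0.3175,
   0.1718,
   0.4085,
   0.0917
  ],
  "1": [
   0.7251,
   0.1649,
   0,
   0.11
  ],
  "2": [
   0.4237,
   0.1906,
   0.3388,
   0.0424
  ],
  "3": [
   0.2496,
   0.1958,
   0.5008,
   0.0552
  ],
  "4": [
   0.0381,
   0.0284,
   0.1248,
   0.8243
  ]
 }
}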