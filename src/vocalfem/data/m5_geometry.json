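{
 "name": "modified-M5 four-layer cross-section",
 "version": 1,
 "outline": [
  [
   0.0,
   -9.0
  ],
  [
   2.0,
   -9.0
  ],
  [
   8.25,
   -3.6
  ],
  [
   8.4,
   0.0
  ],
  [
   7.0,
   1.0
  ],
  [
   0.0,
   1.0
  ]
 ],
 "interfaces": {
  "SLP": [
   [
    0.0,
    -9.0
   ],
   [
    0.0,
    0.7
   ],
   [
    6.9039,
    0.7
   ],
   [
    8.0935,
    -0.1497
   ],
   [
    7.9557,
    -3.4578
   ],
   [
    1.8039,
    -8.773
   ],
   [
    1.7319,
    -8.8653
   ],
   [
    1.7013,
    -9.0
   ]
  ],
  "ligament": [
   [
    0.0,
    -1.3
   ],
   [
    6.0438,
    -1.3
   ],
   [
    5.9934,
    -2.5101
   ],
   [
    0.4963,
    -7.2596
   ],
   [
    0.1857,
    -7.5864
   ],
   [
    0.0,
    -7.8801
   ]
  ],
  "body": [
   [
    0.0,
    -2.0
   ],
   [
    5.3141,
    -2.0
   ],
   [
    5.3066,
    -2.1784
   ],
   [
    0.0,
    -6.7706
   ]
  ]
 },
 "contact_plane_x": 8.4,
 "depth": 14.0,
 "channel": {
  "z_in": -3.6,
  "z_out": 0.0
 }
}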