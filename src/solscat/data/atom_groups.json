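{
 "version": 1,
 "description": "Five-Gaussian X-ray form factors f(q)=sum a_i exp(-b_i q^2) (q in 1/A, b in A^2) for atoms and H-implicit groups, refit from the IT92 tabulation on q in [0,25]; volumes are displaced solvent volumes (A^3), Fraser/Svergun convention.",
 "solvent_ed_default": 0.334,
 "groups": {
  "H": {
   "element": "H",
   "n_h": 0,
   "z": 1,
   "volume": 5.15,
   "a": [
    0.54452545,
    0.25538291,
    0.18797223,
    0.0042797822,
    0.007839627800000026
   ],
   "b": [
    0.078715573,
    0.20942667,
    0.024489573,
    0.76827099,
    0.0025061442
   ]
  },
  "C": {
   "element": "C",
   "n_h": 0,
   "z": 6,
   "volume": 16.44,
   "a": [
    0.34629598,
    1.1762979,
    0.0027787764,
    2.8539552,
    1.6206721436000002
   ],
   "b": [
    0.017930071,
    0.29674868,
    0.0025061442,
    0.10488922,
    0.0025061442
   ]
  },
  "CH": {
   "element": "C",
   "n_h": 1,
   "z": 7,
   "volume": 21.59,
   "a": [
    3.378267,
    0.52374755,
    0.7807913,
    1.4666323,
    0.8505618500000001
   ],
   "b": [
    0.098859735,
    0.019484791,
    0.0025061442,
    0.28133714,
    0.0025061442
   ]
  },
  "CH2": {
   "element": "C",
   "n_h": 2,
   "z": 8,
   "volume": 26.74,
   "a": [
    3.9234191,
    0.70693461,
    0.0031242949,
    1.7303466,
    1.6361753951000004
   ],
   "b": [
    0.09532103,
    0.020474848,
    0.0025061442,
    0.27218365,
    0.0025061442
   ]
  },
  "CH3": {
   "element": "C",
   "n_h": 3,
   "z": 9,
   "volume": 31.89,
   "a": [
    2.1594577,
    4.2327367,
    0.86310471,
    0.097959918,
    1.646740972
   ],
   "b": [
    0.23747605,
    0.089702187,
    0.020786873,
    0.6178691,
    0.0025061442
   ]
  },
  "N": {
   "element": "N",
   "n_h": 0,
   "z": 7,
   "volume": 2.49,
   "a": [
    0.0067503383,
    1.1061063,
    3.96492,
    1.9222233,
    6.169999977601037e-08
   ],
   "b": [
    0.0025061442,
    0.25055367,
    0.076893991,
    0.0025061442,
    0.0025061442
   ]
  },
  "NH": {
   "element": "N",
   "n_h": 1,
   "z": 8,
   "volume": 7.64,
   "a": [
    0.0001250984,
    4.3734493,
    1.6771737,
    1.9492519,
    1.6000001323845936e-09
   ],
   "b": [
    0.0025061442,
    0.070613632,
    0.22240363,
    0.0025061442,
    0.0025061442
   ]
  },
  "NH2": {
   "element": "N",
   "n_h": 2,
   "z": 9,
   "volume": 12.79,
   "a": [
    4.7521761,
    1.9678241,
    4.7799255e-06,
    2.2799951,
    -7.992549910795788e-08
   ],
   "b": [
    0.065837336,
    0.0025061442,
    12.184994,
    0.20537247,
    0.0025061442
   ]
  },
  "NH3": {
   "element": "N",
   "n_h": 3,
   "z": 10,
   "volume": 17.94,
   "a": [
    0.0070418338,
    5.1192276,
    2.8959184,
    1.9778121,
    6.620000014834204e-08
   ],
   "b": [
    0.0025061442,
    0.062127223,
    0.19408665,
    0.0025061442,
    0.0025061442
   ]
  },
  "O": {
   "element": "O",
   "n_h": 0,
   "z": 8,
   "volume": 9.13,
   "a": [
    2.5432143,
    2.6738283,
    0.053415428,
    0.62208995,
    2.1074520220000004
   ],
   "b": [
    0.067406563,
    0.067406561,
    0.0025061442,
    0.29329205,
    0.0025061442
   ]
  },
  "OH": {
   "element": "O",
   "n_h": 1,
   "z": 9,
   "volume": 14.28,
   "a": [
    2.4485076,
    3.3549034,
    0.034290657,
    1.0159104,
    2.1463879429999997
   ],
   "b": [
    0.065131067,
    0.065131066,
    0.0025061442,
    0.2537113,
    0.0025061442
   ]
  },
  "S": {
   "element": "S",
   "n_h": 0,
   "z": 16,
   "volume": 19.86,
   "a": [
    5.0490489,
    6.0580423,
    2.2158826,
    0.10155698,
    2.5754692200000004
   ],
   "b": [
    0.015961877,
    0.19126844,
    0.0025061442,
    1.4632107,
    0.0025061442
   ]
  },
  "SH": {
   "element": "S",
   "n_h": 1,
   "z": 17,
   "volume": 25.01,
   "a": [
    5.3177976,
    6.6831861,
    1.4223371,
    0.19307556,
    3.3836036400000005
   ],
   "b": [
    0.01638055,
    0.18023073,
    0.0025061442,
    1.032899,
    0.0025061442
   ]
  },
  "P": {
   "element": "P",
   "n_h": 0,
   "z": 15,
   "volume": 5.73,
   "a": [
    5.6167164,
    4.492445,
    1.8498859,
    0.60150698,
    2.43944572
   ],
   "b": [
    0.017933915,
    0.249484,
    0.0025061442,
    0.24948456,
    0.0025061442
   ]
  },
  "H2O": {
   "element": "O",
   "n_h": 2,
   "z": 10,
   "volume": 29.9,
   "a": [
    2.10104,
    4.2350193,
    0.025860347,
    1.4646347,
    2.173445653
   ],
   "b": [
    0.063028549,
    0.063028562,
    0.0025061442,
    0.2302869,
    0.0025061442
   ]
  },
  "FE": {
   "element": "Fe",
   "n_h": 0,
   "z": 26,
   "volume": 7.99,
   "a": [
    9.700601,
    4.3225445,
    3.6840842,
    2.2610048,
    6.031765499999999
   ],
   "b": [
    0.048130813,
    0.0025061442,
    0.048130356,
    0.56437196,
    0.0025061442
   ]
  },
  "NA": {
   "element": "Na",
   "n_h": 0,
   "z": 11,
   "volume": 4.45,
   "a": [
    5.0438504,
    1.8925115,
    0.019817741,
    1.1805917,
    2.8632286590000007
   ],
   "b": [
    0.036670482,
    0.036670507,
    0.0025061442,
    0.79304793,
    0.0025061442
   ]
  },
  "MG": {
   "element": "Mg",
   "n_h": 0,
   "z": 12,
   "volume": 1.56,
   "a": [
    4.8236679,
    2.1299608,
    1.2181807,
    1.8836987,
    1.9444918999999992
   ],
   "b": [
    0.029315361,
    0.53709552,
    0.0025061442,
    0.029315454,
    0.0025061442
   ]
  },
  "CL": {
   "element": "Cl",
   "n_h": 0,
   "z": 17,
   "volume": 24.84,
   "a": [
    5.3791455,
    4.4015636,
    7.057062,
    0.16222886,
    4.000000330961484e-08
   ],
   "b": [
    0.0025061442,
    0.014751174,
    0.15311746,
    0.96696571,
    0.0025061442
   ]
  },
  "K": {
   "element": "K",
   "n_h": 0,
   "z": 19,
   "volume": 11.01,
   "a": [
    8.1195647,
    0.96637114,
    1.2145566,
    1.9029947,
    6.79651286
   ],
   "b": [
    0.095696579,
    0.015062804,
    1.2264969,
    0.015062901,
    0.0025061442
   ]
  },
  "CA": {
   "element": "Ca",
   "n_h": 0,
   "z": 20,
   "volume": 4.19,
   "a": [
    2.4987135,
    2.2958285,
    5.3003529,
    2.3355154,
    7.5695897
   ],
   "b": [
    0.075914911,
    0.019777574,
    0.075917295,
    0.81889911,
    0.0025061442
   ]
  },
  "ZN": {
   "element": "Zn",
   "n_h": 0,
   "z": 30,
   "volume": 1.7,
   "a": [
    12.508462,
    0.94017327,
    3.4326549,
    2.0734611,
    11.04524873
   ],
   "b": [
    0.038580077,
    0.0025061442,
    0.038580245,
    0.49685083,
    0.0025061442
   ]
  },
  "MN": {
   "element": "Mn",
   "n_h": 0,
   "z": 25,
   "volume": 2.39,
   "a": [
    11.409561,
    9.8051905,
    1.2775783,
    2.360104,
    0.14756619999999998
   ],
   "b": [
    0.050426303,
    0.0025061442,
    0.050426498,
    0.57338412,
    0.0025061442
   ]
  }
 }
}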