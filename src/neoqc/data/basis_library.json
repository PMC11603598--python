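{
  "sto-3g": {
    "kind": "orbital",
    "elements": {
      "H": [
        {"l": 0, "exps": [3.42525091, 0.62391373, 0.16885540],
         "coefs": [0.15432897, 0.53532814, 0.44463454]}
      ],
      "O": [
        {"l": 0, "exps": [130.7093200, 23.8088610, 6.4436083],
         "coefs": [0.15432897, 0.53532814, 0.44463454]},
        {"l": 0, "exps": [5.0331513, 1.1695961, 0.3803890],
         "coefs": [-0.09996723, 0.39951283, 0.70011547]},
        {"l": 1, "exps": [5.0331513, 1.1695961, 0.3803890],
         "coefs": [0.15591627, 0.60768372, 0.39195739]}
      ],
      "F": [
        {"l": 0, "exps": [166.6791300, 30.3608120, 8.2168207],
         "coefs": [0.15432897, 0.53532814, 0.44463454]},
        {"l": 0, "exps": [6.4648032, 1.5022812, 0.4885885],
         "coefs": [-0.09996723, 0.39951283, 0.70011547]},
        {"l": 1, "exps": [6.4648032, 1.5022812, 0.4885885],
         "coefs": [0.15591627, 0.60768372, 0.39195739]}
      ]
    }
  },
  "6-31g": {
    "kind": "orbital",
    "elements": {
      "H": [
        {"l": 0, "exps": [18.7311370, 2.8253937, 0.6401217],
         "coefs": [0.03349460, 0.23472695, 0.81375733]},
        {"l": 0, "exps": [0.1612778], "coefs": [1.0]}
      ],
      "O": [
        {"l": 0,
         "exps": [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570, 5.7996353],
         "coefs": [0.0018311, 0.0139501, 0.0684451, 0.2327143, 0.4701930, 0.3585209]},
        {"l": 0, "exps": [15.539616, 3.5999336, 1.0137618],
         "coefs": [-0.1107775, -0.1480263, 1.1307670]},
        {"l": 1, "exps": [15.539616, 3.5999336, 1.0137618],
         "coefs": [0.0708743, 0.3397528, 0.7271586]},
        {"l": 0, "exps": [0.2700058], "coefs": [1.0]},
        {"l": 1, "exps": [0.2700058], "coefs": [1.0]}
      ]
    }
  },
  "cc-pvtz": {
    "kind": "orbital",
    "counting_only": true,
    "composition": {"H": "3s2p1d", "O": "4s3p2d1f", "F": "4s3p2d1f",
                    "N": "4s3p2d1f", "C": "4s3p2d1f"}
  },
  "cc-pvtz-mp2fit": {
    "kind": "aux",
    "counting_only": true,
    "composition": {"H": "4s3p2d1f", "O": "8s6p5d3f1g", "F": "8s6p5d3f1g"}
  },
  "cc-pvqz-mp2fit": {
    "kind": "aux",
    "counting_only": true,
    "composition": {"H": "5s4p3d2f1g", "O": "8s7p6d5f3g1h", "F": "8s7p6d5f3g1h"}
  },
  "pb4-f2": {
    "kind": "nuclear",
    "comment": "4s3p2d2f protonic basis; composition fixed at 37 spherical functions per quantum proton. Exponents are SYNTHETIC even-tempered stand-ins centred on the harmonic-well optimum for a proton (published primitives unavailable offline).",
    "elements": {
      "H": [
        {"l": 0, "exps": [45.254834, 22.627417, 11.3137085, 5.65685425], "coefs": null},
        {"l": 1, "exps": [32.0, 16.0, 8.0], "coefs": null},
        {"l": 2, "exps": [22.627417, 11.3137085], "coefs": null},
        {"l": 3, "exps": [16.0, 8.0], "coefs": null}
      ]
    }
  },
  "prot-1s": {
    "kind": "nuclear",
    "comment": "minimal protonic test basis",
    "elements": {"H": [{"l": 0, "exps": [12.0], "coefs": null}]}
  },
  "prot-sp": {
    "kind": "nuclear",
    "comment": "small protonic test basis, 2s1p = 5 functions",
    "elements": {"H": [
      {"l": 0, "exps": [16.0, 8.0], "coefs": null},
      {"l": 1, "exps": [12.0], "coefs": null}
    ]}
  },
  "prot-spd": {
    "kind": "nuclear",
    "comment": "medium protonic test basis, 3s2p1d = 14 functions",
    "elements": {"H": [
      {"l": 0, "exps": [20.0, 10.0, 5.0], "coefs": null},
      {"l": 1, "exps": [16.0, 8.0], "coefs": null},
      {"l": 2, "exps": [12.0], "coefs": null}
    ]}
  }
}
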