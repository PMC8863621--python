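{
  "description": "Dose-effect anchor tables for TPS beam-model parameters of a 6 MV Varian Base class linac equipped with a Millennium120 MLC. Each anchor row is [community percentile, parameter value, systematic dose effect in % relative to the community median]. The 2.5th/10th/90th/97.5th rows carry surveyed community parameter values and their phantom dose effects; the 50th-percentile parameter values are configuration defaults, not survey data: because the dose response is linear in the parameter value, each default median is placed at the zero-effect abscissa implied by the flanking 10th/90th anchors (or at their value midpoint when the response is flat or one-sided). A positive effect means the TPS overestimates dose relative to delivery.",
  "linac_class": "Varian Base",
  "beam_energy": "6 MV",
  "mlc_model": "Millennium120",
  "tps": {
    "Eclipse AAA": [
      {
        "names": [
          "Effective Target Spot Size X",
          "Effective Target Spot Size Y"
        ],
        "units": "mm",
        "anchors": [
          [
            2.5,
            0.0,
            0.0
          ],
          [
            10,
            0.0,
            0.0
          ],
          [
            50,
            0.25,
            0.0
          ],
          [
            90,
            0.5,
            0.0
          ],
          [
            97.5,
            1.0,
            0.0
          ]
        ]
      },
      {
        "names": [
          "MLC Transmission Factor"
        ],
        "units": "",
        "anchors": [
          [
            2.5,
            0.0118,
            -1.1
          ],
          [
            10,
            0.0134,
            -0.7
          ],
          [
            50,
            0.01648,
            0.0
          ],
          [
            90,
            0.02,
            0.8
          ],
          [
            97.5,
            0.02,
            0.8
          ]
        ]
      },
      {
        "names": [
          "Dosimetric Leaf Gap"
        ],
        "units": "cm",
        "anchors": [
          [
            2.5,
            0.1,
            -3.6
          ],
          [
            10,
            0.1388,
            -1.5
          ],
          [
            50,
            0.1728,
            0.0
          ],
          [
            90,
            0.2,
            1.2
          ],
          [
            97.5,
            0.23,
            2.8
          ]
        ]
      }
    ],
    "RayStation": [
      {
        "names": [
          "Primary Source X Width",
          "Primary Source Y Width"
        ],
        "units": "cm",
        "anchors": [
          [
            2.5,
            0.04,
            0.0
          ],
          [
            10,
            0.05,
            0.0
          ],
          [
            50,
            0.0735,
            0.0
          ],
          [
            90,
            0.097,
            0.0
          ],
          [
            97.5,
            0.12345,
            0.0
          ]
        ]
      },
      {
        "names": [
          "MLC Transmission"
        ],
        "units": "",
        "anchors": [
          [
            2.5,
            0.007,
            -4.0
          ],
          [
            10,
            0.007,
            -4.0
          ],
          [
            50,
            0.01842857142857143,
            0.0
          ],
          [
            90,
            0.025,
            2.3
          ],
          [
            97.5,
            0.025,
            2.3
          ]
        ]
      },
      {
        "names": [
          "Tongue and Groove"
        ],
        "units": "cm",
        "anchors": [
          [
            2.5,
            0.01,
            1.1
          ],
          [
            10,
            0.01,
            1.1
          ],
          [
            50,
            0.04142857142857143,
            0.0
          ],
          [
            90,
            0.05,
            -0.3
          ],
          [
            97.5,
            0.05,
            -0.3
          ]
        ]
      },
      {
        "names": [
          "Leaf Tip Width"
        ],
        "units": "cm",
        "anchors": [
          [
            2.5,
            0.177,
            -1.6
          ],
          [
            10,
            0.186,
            -1.4
          ],
          [
            50,
            0.3192121212121212,
            0.0
          ],
          [
            90,
            0.5,
            1.9
          ],
          [
            97.5,
            0.5,
            1.9
          ]
        ]
      },
      {
        "names": [
          "MLC Position Offset"
        ],
        "units": "cm",
        "anchors": [
          [
            2.5,
            0.0,
            -3.6
          ],
          [
            10,
            0.0,
            -3.6
          ],
          [
            50,
            0.04054368932038835,
            0.0
          ],
          [
            90,
            0.116,
            6.7
          ],
          [
            97.5,
            0.116,
            6.7
          ]
        ]
      },
      {
        "names": [
          "MLC Position Gain"
        ],
        "units": "",
        "anchors": [
          [
            2.5,
            0.0,
            0.0
          ],
          [
            10,
            0.0,
            0.0
          ],
          [
            50,
            0.0075,
            0.0
          ],
          [
            90,
            0.015,
            0.0
          ],
          [
            97.5,
            0.015,
            0.0
          ]
        ]
      },
      {
        "names": [
          "MLC Position Curvature"
        ],
        "units": "1/cm",
        "anchors": [
          [
            2.5,
            0.0,
            0.0
          ],
          [
            10,
            0.0,
            0.0
          ],
          [
            50,
            0.0005,
            0.0
          ],
          [
            90,
            0.001,
            0.2
          ],
          [
            97.5,
            0.001,
            0.2
          ]
        ]
      }
    ]
  }
}
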