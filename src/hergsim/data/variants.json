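{
  "schema": "hergsim.variants/1",
  "comment": "Kinetic medians of the four measured channel populations. Time-constant curves are monotone anchor sets: the anchored voltages carry the measured medians; the remaining anchors encode the voltage dependence seen in the recordings (activation speeds up, deactivation slows, inactivation speeds up with depolarization; recovery slows toward less negative voltages). Variant curves are the wild-type shape rescaled through the variant's measured anchors. tail_target pins g_max: the activation-protocol tail current at the stated prepulse voltage.",
  "groups": {
    "WT": {
      "v_half_act": -2.76,
      "k_act": 8.5,
      "v_half_inact": -60.4,
      "k_inact": 23.1,
      "tau_act_curve": {
        "v_mv": [
          -50,
          -30,
          -10,
          10,
          30,
          50
        ],
        "tau_ms": [
          900.0,
          520.0,
          340.0,
          230.0,
          164.4,
          130.0
        ]
      },
      "tau_deact_curve": {
        "v_mv": [
          -120,
          -90,
          -60,
          -30,
          0
        ],
        "tau_ms": [
          45.0,
          122.1,
          290.0,
          620.0,
          1200.0
        ]
      },
      "tau_inact_curve": {
        "v_mv": [
          -60,
          -30,
          0,
          30,
          60
        ],
        "tau_ms": [
          12.5,
          8.8,
          5.84,
          3.6,
          2.4
        ]
      },
      "tau_rec_curve": {
        "v_mv": [
          -120,
          -80,
          -50,
          -20
        ],
        "tau_ms": [
          0.25,
          1.38,
          2.9,
          4.63
        ]
      },
      "tail_target": {
        "v_mv": 30,
        "i_pa": 362.7
      },
      "c_m_pf": {
        "median": 13.6,
        "q1": 12.7,
        "q3": 18.0
      },
      "r_a_mohm": {
        "median": 4.24,
        "q1": 3.6,
        "q3": 6.3
      },
      "n_cells": 15
    },
    "S1021Qfs*98": {
      "v_half_act": 7.3,
      "k_act": 9.58,
      "v_half_inact": -54.2,
      "k_inact": 27.4,
      "tau_act_curve": {
        "v_mv": [
          -50,
          -30,
          -10,
          10,
          30,
          50
        ],
        "tau_ms": [
          587.4,
          339.4,
          221.9,
          150.1,
          107.3,
          84.9
        ]
      },
      "tau_deact_curve": {
        "v_mv": [
          -120,
          -90,
          -60,
          -30,
          0
        ],
        "tau_ms": [
          56.8,
          154.1,
          366.0,
          782.5,
          1514.5
        ]
      },
      "tau_inact_curve": {
        "v_mv": [
          -60,
          -30,
          0,
          30,
          60
        ],
        "tau_ms": [
          19.4,
          13.6,
          9.05,
          5.58,
          3.72
        ]
      },
      "tau_rec_curve": {
        "v_mv": [
          -120,
          -80,
          -50,
          -20
        ],
        "tau_ms": [
          0.083,
          0.46,
          1.098,
          1.99
        ]
      },
      "tail_target": {
        "v_mv": 30,
        "i_pa": 110.5
      },
      "c_m_pf": {
        "median": 19.4,
        "q1": 9.9,
        "q3": 25.5
      },
      "r_a_mohm": {
        "median": 3.44,
        "q1": 2.99,
        "q3": 4.98
      },
      "n_cells": 14
    },
    "A228V": {
      "v_half_act": -5.79,
      "k_act": 9.63,
      "v_half_inact": -60.8,
      "k_inact": 27.0,
      "tau_act_curve": {
        "v_mv": [
          -50,
          -30,
          -10,
          10,
          30,
          50
        ],
        "tau_ms": [
          1020.4,
          589.6,
          385.5,
          260.8,
          186.4,
          147.4
        ]
      },
      "tau_deact_curve": {
        "v_mv": [
          -120,
          -90,
          -60,
          -30,
          0
        ],
        "tau_ms": [
          46.2,
          125.3,
          297.6,
          636.2,
          1231.4
        ]
      },
      "tau_inact_curve": {
        "v_mv": [
          -60,
          -30,
          0,
          30,
          60
        ],
        "tau_ms": [
          7.9,
          5.56,
          3.69,
          2.27,
          1.52
        ]
      },
      "tau_rec_curve": {
        "v_mv": [
          -120,
          -80,
          -50,
          -20
        ],
        "tau_ms": [
          0.252,
          1.39,
          2.381,
          3.1
        ]
      },
      "tail_target": {
        "v_mv": 30,
        "i_pa": 322.9
      },
      "c_m_pf": {
        "median": 15.3,
        "q1": 10.7,
        "q3": 24.1
      },
      "r_a_mohm": {
        "median": 3.52,
        "q1": 2.9,
        "q3": 4.98
      },
      "n_cells": 13
    },
    "S1021Qfs*98/A228V": {
      "v_half_act": -5.5,
      "k_act": 8.54,
      "v_half_inact": -64.9,
      "k_inact": 24.4,
      "tau_act_curve": {
        "v_mv": [
          -50,
          -30,
          -10,
          10,
          30,
          50
        ],
        "tau_ms": [
          617.5,
          356.8,
          233.3,
          157.8,
          112.8,
          89.2
        ]
      },
      "tau_deact_curve": {
        "v_mv": [
          -120,
          -90,
          -60,
          -30,
          0
        ],
        "tau_ms": [
          69.3,
          188.0,
          446.5,
          954.6,
          1847.6
        ]
      },
      "tau_inact_curve": {
        "v_mv": [
          -60,
          -30,
          0,
          30,
          60
        ],
        "tau_ms": [
          7.62,
          5.36,
          3.56,
          2.19,
          1.46
        ]
      },
      "tau_rec_curve": {
        "v_mv": [
          -120,
          -80,
          -50,
          -20
        ],
        "tau_ms": [
          0.176,
          0.97,
          1.829,
          2.62
        ]
      },
      "tail_target": {
        "v_mv": 30,
        "i_pa": 111.8
      },
      "c_m_pf": {
        "median": 17.8,
        "q1": 9.5,
        "q3": 24.7
      },
      "r_a_mohm": {
        "median": 4.42,
        "q1": 2.86,
        "q3": 6.29
      },
      "n_cells": 14
    }
  }
}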