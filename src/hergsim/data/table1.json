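{
  "schema": "hergsim.group_reference/1",
  "comment": "Measured biophysical characteristics of the four channel populations: median (q1, q3) and group size per parameter. Used as the reference for summary reports and to set the cell-to-cell variability of the synthetic cohorts.",
  "parameters": {
    "c_m_pf": {
      "WT": {"median": 13.6, "q1": 12.7, "q3": 18.0, "n": 15},
      "S1021Qfs*98": {"median": 19.4, "q1": 9.9, "q3": 25.5, "n": 14},
      "A228V": {"median": 15.3, "q1": 10.7, "q3": 24.1, "n": 13},
      "S1021Qfs*98/A228V": {"median": 17.8, "q1": 9.5, "q3": 24.7, "n": 14}
    },
    "r_a_mohm": {
      "WT": {"median": 4.24, "q1": 3.60, "q3": 6.30, "n": 15},
      "S1021Qfs*98": {"median": 3.44, "q1": 2.99, "q3": 4.98, "n": 14},
      "A228V": {"median": 3.52, "q1": 2.90, "q3": 4.98, "n": 13},
      "S1021Qfs*98/A228V": {"median": 4.42, "q1": 2.86, "q3": 6.29, "n": 14}
    },
    "i_tail_30mv_pa": {
      "WT": {"median": 362.7, "q1": 231.2, "q3": 489.2, "n": 15},
      "S1021Qfs*98": {"median": 110.5, "q1": 58.3, "q3": 157.2, "n": 14},
      "A228V": {"median": 322.9, "q1": 262.5, "q3": 530.7, "n": 13},
      "S1021Qfs*98/A228V": {"median": 111.8, "q1": 62.9, "q3": 229.2, "n": 14}
    },
    "v_half_act_mv": {
      "WT": {"median": -2.76, "q1": -10.0, "q3": 12.48, "n": 15},
      "S1021Qfs*98": {"median": 7.30, "q1": 2.69, "q3": 14.73, "n": 14},
      "A228V": {"median": -5.79, "q1": -9.77, "q3": 3.34, "n": 13},
      "S1021Qfs*98/A228V": {"median": -5.5, "q1": -11.54, "q3": -1.78, "n": 14}
    },
    "k_act_mv": {
      "WT": {"median": 8.50, "q1": 7.7, "q3": 10.09, "n": 15},
      "S1021Qfs*98": {"median": 9.58, "q1": 8.68, "q3": 13.24, "n": 14},
      "A228V": {"median": 9.63, "q1": 7.99, "q3": 11.30, "n": 13},
      "S1021Qfs*98/A228V": {"median": 8.54, "q1": 7.85, "q3": 9.06, "n": 14}
    },
    "tau_act_30mv_ms": {
      "WT": {"median": 164.4, "q1": 99.4, "q3": 368.0, "n": 15},
      "S1021Qfs*98": {"median": 107.3, "q1": 63.5, "q3": 210.4, "n": 9},
      "A228V": {"median": 186.4, "q1": 98.6, "q3": 238.8, "n": 13},
      "S1021Qfs*98/A228V": {"median": 112.8, "q1": 67.3, "q3": 158.9, "n": 14}
    },
    "tau_deact_m90mv_ms": {
      "WT": {"median": 122.1, "q1": 77.0, "q3": 211.0, "n": 15},
      "S1021Qfs*98": {"median": 154.1, "q1": 123.6, "q3": 227.9, "n": 15},
      "A228V": {"median": 125.3, "q1": 60.4, "q3": 218.9, "n": 12},
      "S1021Qfs*98/A228V": {"median": 188.0, "q1": 109.5, "q3": 201.0, "n": 9}
    },
    "v_half_inact_mv": {
      "WT": {"median": -60.4, "q1": -63.1, "q3": -52.2, "n": 14},
      "S1021Qfs*98": {"median": -54.2, "q1": -71.2, "q3": -46.8, "n": 10},
      "A228V": {"median": -60.8, "q1": -66.9, "q3": -48.6, "n": 19},
      "S1021Qfs*98/A228V": {"median": -64.9, "q1": -68.6, "q3": -63.0, "n": 17}
    },
    "k_inact_mv": {
      "WT": {"median": 23.1, "q1": 22.4, "q3": 26.6, "n": 14},
      "S1021Qfs*98": {"median": 27.4, "q1": 25.0, "q3": 37.1, "n": 10},
      "A228V": {"median": 27.0, "q1": 23.9, "q3": 31.3, "n": 19},
      "S1021Qfs*98/A228V": {"median": 24.4, "q1": 22.0, "q3": 28.2, "n": 17}
    },
    "tau_inact_0mv_ms": {
      "WT": {"median": 5.84, "q1": 3.64, "q3": 7.08, "n": 14},
      "S1021Qfs*98": {"median": 9.05, "q1": 7.90, "q3": 10.67, "n": 10},
      "A228V": {"median": 3.69, "q1": 3.21, "q3": 4.40, "n": 17},
      "S1021Qfs*98/A228V": {"median": 3.56, "q1": 2.63, "q3": 4.73, "n": 11}
    },
    "tau_rec_m80mv_ms": {
      "WT": {"median": 1.38, "q1": 0.27, "q3": 2.20, "n": 14},
      "S1021Qfs*98": {"median": 0.46, "q1": 0.27, "q3": 0.64, "n": 10},
      "A228V": {"median": 1.39, "q1": 0.93, "q3": 1.85, "n": 19},
      "S1021Qfs*98/A228V": {"median": 0.97, "q1": 0.80, "q3": 1.18, "n": 15}
    },
    "tau_rec_m20mv_ms": {
      "WT": {"median": 4.63, "q1": 4.03, "q3": 4.96, "n": 14},
      "S1021Qfs*98": {"median": 1.99, "q1": 1.80, "q3": 3.06, "n": 10},
      "A228V": {"median": 3.10, "q1": 2.47, "q3": 3.34, "n": 19},
      "S1021Qfs*98/A228V": {"median": 2.62, "q1": 2.25, "q3": 3.17, "n": 15}
    }
  }
}
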