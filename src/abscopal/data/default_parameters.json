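{
  "death_rates": {
    "APC": 0.3,
    "DC": 0.3,
    "M1": 0.2,
    "M2": 0.2,
    "TE1": 0.2,
    "TREG": 0.2
  },
  "source_rates": {
    "APC": 0.0,
    "DC": 600000.0,
    "M1": 600000.0,
    "M2": 400000.0,
    "TE1": 0.0,
    "TREG": 400000.0
  },
  "units": {
    "a_c": "1/Gy",
    "a_im": "1/Gy",
    "ac_dc": "mL/cell/day",
    "ac_dead_dc": "mL/cell/day",
    "ac_dead_m1": "mL/cell/day",
    "ac_m1": "mL/cell/day",
    "b_c": "1/Gy^2",
    "b_im": "1/Gy^2",
    "clear_c_dead": "1/day",
    "k_prol_tn": "1/day",
    "k_rc1_control": "mL/cell/day",
    "k_rc1_rt": "mL/cell/day",
    "k_tn_control": "mL/cell/day",
    "k_tn_rt": "mL/cell/day",
    "lg_tumor": "1/day",
    "n_exp": "dimensionless",
    "s_m2": "mL/cell",
    "s_treg": "mL/cell",
    "tn0": "cells",
    "v_cell_mm3": "mm^3/cell",
    "vi_tumor0_mm3": "mm^3"
  },
  "values": {
    "a_c": 0.3,
    "a_im": 0.6,
    "ac_dc": 2.5e-10,
    "ac_dead_dc": 2.5e-10,
    "ac_dead_m1": 8e-11,
    "ac_m1": 8e-11,
    "b_c": 0.03,
    "b_im": 0.06,
    "clear_c_dead": 0.4,
    "k_prol_tn": 0.5,
    "k_rc1_control": 8e-07,
    "k_rc1_rt": 1.5e-06,
    "k_tn_control": 7e-11,
    "k_tn_rt": 3.5e-10,
    "lg_tumor": 0.18,
    "n_exp": 240000.0,
    "s_m2": 1e-07,
    "s_treg": 1e-07,
    "tn0": 1000000.0,
    "v_cell_mm3": 1e-06,
    "vi_tumor0_mm3": 30.0
  }
}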