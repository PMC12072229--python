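name: adefovir
physchem:
  molecular_weight_g_mol: 273.19
  compound_class: ampholyte
  pka_list:
  - 2.0
  - 6.8
  logp_ow: -1.8
  blood_to_plasma_ratio: 0.8
  fu_plasma: 0.96
absorption:
  ka_per_h: 0.1365
  fa: 0.47
  lag_time_h: 0.0
transporters:
  clint_oat1_invitro_ul_min_1e6: 7.264
  ref_oat1: 2.0
  cl_mrp4_ul_min_1e6: 1.0
  clpd_baso_ul_min_1e6: 0.15
  clpd_apical_ul_min_1e6: 0.15
elimination:
  cl_nonrenal_linear_l_h: 0.0
kp_scalar: 1.7447
schema_version: 1
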