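name: probenecid
physchem:
  molecular_weight_g_mol: 285.36
  compound_class: monoprotic acid
  pka_list:
  - 3.3
  logp_ow: 3.21
  blood_to_plasma_ratio: 0.6
  fu_plasma: 0.1
absorption:
  ka_per_h: 0.8
  fa: 1.0
  lag_time_h: 0.0
transporters:
  clint_oat1_invitro_ul_min_1e6: 0.0
  ref_oat1: 1.0
  cl_mrp4_ul_min_1e6: 0.0
  clpd_baso_ul_min_1e6: 0.0
  clpd_apical_ul_min_1e6: 0.0
elimination:
  cl_nonrenal_linear_l_h: 0.0
  vmax_nonrenal_mg_h: 16.84
  km_nonrenal_mg_l: 25.0
kp_scalar: 0.6631
oat13_ki_unbound_um: 3.4
schema_version: 1
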