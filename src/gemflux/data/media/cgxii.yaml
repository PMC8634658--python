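# CGXII minimal medium (Keilhauer-style defined medium for C. glutamicum),
# expressed as BiGG exchange-reaction ids with a uniform uptake magnitude of
# 10 mmol gDW^-1 h^-1.  Protocatechuate (34dhbz) is part of the recipe as an
# iron chelator.  Oxygen is governed by the aerobic switch, not this list.
name: CGXII
carbon_source: EX_glc__D_e
components:
  EX_glc__D_e: 10
  EX_nh4_e: 10
  EX_urea_e: 10
  EX_pi_e: 10
  EX_k_e: 10
  EX_so4_e: 10
  EX_mg2_e: 10
  EX_ca2_e: 10
  EX_cl_e: 10
  EX_na1_e: 10
  EX_fe2_e: 10
  EX_fe3_e: 10
  EX_mn2_e: 10
  EX_zn2_e: 10
  EX_cu2_e: 10
  EX_ni2_e: 10
  EX_mobd_e: 10
  EX_btn_e: 10
  EX_34dhbz_e: 10
  EX_h_e: 10
  EX_h2o_e: 10
notes: >-
  Chemically defined minimal medium; glucose is the designated carbon source
  and can be swapped for other sources in carbon-source scans.
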