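# Chemically defined APPROXIMATION of lysogeny broth: amino acids,
# nucleobases, glucose and salts.  LB has no exact chemical definition, so
# this file is a stand-in for qualitative complete-medium simulations and is
# deliberately excluded from any quantitative comparison.
name: LB-approximation
carbon_source: EX_glc__D_e
components:
  EX_glc__D_e: 10
  EX_ala__L_e: 10
  EX_arg__L_e: 10
  EX_asn__L_e: 10
  EX_asp__L_e: 10
  EX_cys__L_e: 10
  EX_glu__L_e: 10
  EX_gln__L_e: 10
  EX_gly_e: 10
  EX_his__L_e: 10
  EX_ile__L_e: 10
  EX_leu__L_e: 10
  EX_lys__L_e: 10
  EX_met__L_e: 10
  EX_phe__L_e: 10
  EX_pro__L_e: 10
  EX_ser__L_e: 10
  EX_thr__L_e: 10
  EX_trp__L_e: 10
  EX_tyr__L_e: 10
  EX_val__L_e: 10
  EX_ade_e: 10
  EX_gua_e: 10
  EX_csn_e: 10
  EX_ura_e: 10
  EX_thymd_e: 10
  EX_nh4_e: 10
  EX_pi_e: 10
  EX_k_e: 10
  EX_na1_e: 10
  EX_cl_e: 10
  EX_so4_e: 10
  EX_mg2_e: 10
  EX_ca2_e: 10
  EX_fe2_e: 10
  EX_fe3_e: 10
  EX_mn2_e: 10
  EX_zn2_e: 10
  EX_cu2_e: 10
  EX_ni2_e: 10
  EX_h_e: 10
  EX_h2o_e: 10
notes: Approximation; not suitable for quantitative growth-rate comparison.
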