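{
  "raf_tot": 1.0,
  "mek_tot": 1.0,
  "erk_tot": 1.0,
  "nfb_tot": 1.0,
  "pfb_tot": 1.0,
  "phos_tot": 1.0,
  "k_ract": 0.12,
  "k_rdeact": 0.35,
  "k_egf": 0.1,
  "k_ngf": 0.2,
  "k_rsyn": 0.0014440607,
  "k_rdeg": 0.0014440607,
  "k_int": 0.22,
  "k_rec": 0.044,
  "t_half_internal": 30.0,
  "raf_basal_act": 0.002,
  "k_raf_act": 9.0,
  "km_raf_act": 0.3,
  "v_raf_deact": 0.35,
  "km_raf_deact": 0.3,
  "k_mek_act": 1.0,
  "km_mek_act": 0.3,
  "v_mek_deact": 0.4,
  "km_mek_deact": 0.3,
  "k_erk_act": 1.0,
  "km_erk_act": 0.3,
  "v_erk_deact": 0.45,
  "km_erk_deact": 0.3,
  "k3_f": 0.0286,
  "nfb_gain_scale": 26.0,
  "nfb_deact": 0.2,
  "nfb_basal": 0.25,
  "nfb_ffw_k": 0.244,
  "nfb_ffw_h": 18.0,
  "nfb_raf_gain": 8.0,
  "k_pfb_act": 0.07,
  "k_pfb_deact": 0.008,
  "pfb_basal": 0.04,
  "pfb_ffw_vmax": 1.0,
  "pfb_ffw_k": 0.2465,
  "pfb_ffw_h": 48.0,
  "pfb_raf_gain": 5.5,
  "nd_erk_raf_gain": 1.0,
  "dusp_mrna_syn": 0.012,
  "dusp_translation": 0.02,
  "dusp_mrna_deg": 0.0077016,
  "dusp_prot_deg": 0.0077016,
  "dusp_kcat": 0.08,
  "dusp_km": 0.3,
  "pfb_erk_km": 0.2,
  "nfb_inh_h": 2.0,
  "nfb_erk_km": 0.1,
  "nfb_self_km": 0.38,
  "pfb_pos_km": 0.09
}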