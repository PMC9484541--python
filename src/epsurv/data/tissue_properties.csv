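organ,sigma_s_m,rho_kg_m3,c_j_kg_c,k_w_m_c,w_b_ml_min_kg,q_met_w_kg
esophagus,0.511,1040.000,3500.000,0.530,190.000,2.940
stomach,0.511,1088.000,3690.000,0.525,460.320,7.130
colon,0.012,1088.000,3655.000,0.540,765.000,11.850
bile_duct,0.900,1070.500,3716.000,0.521,30.000,0.465
liver,0.028,1078.750,3540.200,0.519,860.500,9.931
pancreas,0.511,1086.500,3164.000,0.512,767.500,11.886
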