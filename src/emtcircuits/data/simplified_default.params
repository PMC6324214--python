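# miR-200/ZEB1 circuit, molecule-count / hour units
g_u200 2100.0
g_mZ 11.0
g_Z 100.0
k_u200 0.05
k_mZ 0.5
k_Z 0.1
h_S_u200_X0 180000.0
h_S_u200_n 2.0
h_S_u200_lam 0.1
h_S_mZ_X0 180000.0
h_S_mZ_n 2.0
h_S_mZ_lam 10.0
h_Z_u200_X0 220000.0
h_Z_u200_n 3.0
h_Z_u200_lam 0.1
h_Z_mZ_X0 25000.0
h_Z_mZ_n 2.0
h_Z_mZ_lam 7.5
mir_u200_mZ_mu0 10000.0
mir_u200_mZ_sites 6.0
mir_u200_mZ_l1 0.6
mir_u200_mZ_l2 0.3
mir_u200_mZ_l3 0.1
mir_u200_mZ_l4 0.05
mir_u200_mZ_l5 0.05
mir_u200_mZ_l6 0.05
mir_u200_mZ_gm1 0.04
mir_u200_mZ_gm2 0.2
mir_u200_mZ_gm3 1.0
mir_u200_mZ_gm4 1.0
mir_u200_mZ_gm5 1.0
mir_u200_mZ_gm6 1.0
mir_u200_mZ_gu1 0.005
mir_u200_mZ_gu2 0.05
mir_u200_mZ_gu3 0.5
mir_u200_mZ_gu4 0.5
mir_u200_mZ_gu5 0.5
mir_u200_mZ_gu6 0.5
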