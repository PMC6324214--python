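# miR-200/ZEB1/ESRP1/HAS2/CD44 circuit, molecule-count / hour units.
# miR-200/ZEB1 core inherited from the simplified circuit; the five new-edge
# blocks calibrated so the five-phase SNAIL response and the ZEB1-mRNA branch
# ranges hold (docs/methods.md).
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
# ESRP1 (repressed by ZEB1)
g_E1 20.0
k_E1 0.1
h_Z_E1_X0 25000.0
h_Z_E1_n 2.0
h_Z_E1_lam 0.1
# CD44 splicing partition controlled by ESRP1
g_C 90.0
k_Cs 0.1
k_Cv 0.1
spl_X0 60.0
spl_n 2.0
# CD44 isoform action on ZEB1 transcription
h_Cs_mZ_X0 126.0
h_Cs_mZ_n 2.0
h_Cs_mZ_lam 2.0
h_Cv_mZ_X0 684.0
h_Cv_mZ_n 2.0
h_Cv_mZ_lam 0.3
# HAS2 / hyaluronic acid branch (HA acts on ZEB1 in complex with CD44s)
g_H2 10.0
k_H2 0.1
h_Z_H2_X0 25000.0
h_Z_H2_n 2.0
h_Z_H2_lam 5.0
g_HA 10.0
k_HA 0.1
h_H2_HA_X0 250.0
h_H2_HA_n 4.0
h_H2_HA_lam 5.0
# threshold in molecules^2 (input is the HA*CD44s product)
h_HA_mZ_X0 15500.0
h_HA_mZ_n 2.0
h_HA_mZ_lam 3.9
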