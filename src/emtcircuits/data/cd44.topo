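# miR-200/ZEB/ESRP1/CD44 reduction used for random-parameter ensembles
# (no HAS2/HA branch, no external SNAIL input).
node u200 microRNA
node mZ mRNA
node Z protein mZ
node E1 protein
node Cs protein
node Cv protein
Z u200 inhibition transcriptional
u200 mZ inhibition microRNA_translational
Z E1 inhibition transcriptional
E1 Cs inhibition splicing
E1 Cv activation splicing
Cs mZ activation nontranscriptional
Cv mZ inhibition nontranscriptional
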