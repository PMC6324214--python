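# miR-200/ZEB1/ESRP1/HAS2/CD44 circuit driven by SNAIL.
# ZEB1 self-activation is mechanistic: ZEB1 represses ESRP1, which shifts the
# CD44 splicing balance toward CD44s; CD44s activates ZEB1 while CD44v
# inhibits it; ZEB1 also drives HAS2 -> hyaluronic acid, which activates ZEB1
# only in complex with CD44s (the @Cs cofactor annotation).
node u200 microRNA
node mZ mRNA
node Z protein mZ
node E1 protein
node H2 protein
node HA metabolite
node Cs protein
node Cv protein
control S
S u200 inhibition transcriptional
S mZ activation transcriptional
Z u200 inhibition transcriptional
u200 mZ inhibition microRNA_translational
Z E1 inhibition transcriptional
E1 Cs inhibition splicing
E1 Cv activation splicing
Cs mZ activation nontranscriptional
Cv mZ inhibition nontranscriptional
Z H2 activation transcriptional
H2 HA activation nontranscriptional
HA mZ activation nontranscriptional @Cs
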