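# miR-200/ZEB1 mutual-inhibition circuit driven by SNAIL,
# with direct ZEB1 transcriptional self-activation.
node u200 microRNA
node mZ mRNA
node Z protein mZ
control S
S u200 inhibition transcriptional
S mZ activation transcriptional
Z u200 inhibition transcriptional
Z mZ activation transcriptional
u200 mZ inhibition microRNA_translational
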