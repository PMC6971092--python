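# EMBOSS iep default pKa set.
group	pka	charge
nterm	8.6	1
cterm	3.6	-1
D	3.9	-1
E	4.1	-1
C	8.5	-1
Y	10.1	-1
H	6.5	1
K	10.8	1
R	12.5	1
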