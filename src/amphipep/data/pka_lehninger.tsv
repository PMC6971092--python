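# Lehninger-style pKa set. "group" is nterm, cterm or a residue letter;
# "charge" is the sign of the group when protonated (+1) or deprotonated (-1).
group	pka	charge
nterm	9.69	1
cterm	2.34	-1
D	3.65	-1
E	4.25	-1
C	8.18	-1
Y	10.07	-1
H	6.00	1
K	10.53	1
R	12.48	1
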