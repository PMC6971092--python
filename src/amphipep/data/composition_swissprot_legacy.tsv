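# Average amino-acid composition of an early-2000s UniProtKB/Swiss-Prot release
# (the era of the classic random-sequence generators). Percent values; they are
# renormalized to sum to 1 on load.
residue	frequency
A	8.3
R	5.7
N	4.4
D	5.3
C	1.7
Q	4.0
E	6.2
G	7.2
H	2.2
I	5.2
L	9.1
K	5.7
M	2.4
F	3.9
P	5.1
S	7.0
T	5.8
W	1.3
Y	3.2
V	6.5
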