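residue	Tiny	Small	Aliphatic	Aromatic	NonPolar	Polar	Charged	Basic	Acidic
A	1	1	1	0	1	0	0	0	0
R	0	0	0	0	0	1	1	1	0
N	0	1	0	0	0	1	0	0	0
D	0	1	0	0	0	1	1	0	1
C	1	1	0	0	1	0	0	0	0
Q	0	0	0	0	0	1	0	0	0
E	0	0	0	0	0	1	1	0	1
G	1	1	0	0	1	0	0	0	0
H	0	0	0	1	0	1	1	1	0
I	0	0	1	0	1	0	0	0	0
L	0	0	1	0	1	0	0	0	0
K	0	0	0	0	0	1	1	1	0
M	0	0	0	0	1	0	0	0	0
F	0	0	0	1	1	0	0	0	0
P	0	1	0	0	1	0	0	0	0
S	1	1	0	0	0	1	0	0	0
T	1	1	0	0	0	1	0	0	0
W	0	0	0	1	1	0	0	0	0
Y	0	0	0	1	1	0	0	0	0
V	0	1	1	0	1	0	0	0	0
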