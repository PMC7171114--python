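residue	hydrophobicity	hydrophilicity	side_chain_mass
A	0.62	-0.5	15.0
R	-2.53	3.0	101.0
N	-0.78	0.2	58.0
D	-0.90	3.0	59.0
C	0.29	-1.0	47.0
Q	-0.85	0.2	72.0
E	-0.74	3.0	73.0
G	0.48	0.0	1.0
H	-0.40	-0.5	82.0
I	1.38	-1.8	57.0
L	1.06	-1.8	57.0
K	-1.50	3.0	73.0
M	0.64	-1.3	75.0
F	1.19	-2.5	91.0
P	0.12	0.0	42.0
S	-0.18	0.3	31.0
T	-0.05	-0.4	45.0
W	0.81	-3.4	130.0
Y	0.26	-2.3	107.0
V	1.08	-1.5	43.0
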