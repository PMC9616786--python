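aa	halpha_rc	calpha_rc
A	4.32	52.5
C	4.55	58.2
D	4.64	54.2
E	4.35	56.6
F	4.62	57.7
G	3.96	45.1
H	4.73	55.0
I	4.17	61.1
K	4.32	56.2
L	4.34	55.1
M	4.48	55.4
N	4.74	53.1
P	4.42	63.3
Q	4.34	55.7
R	4.34	56.0
S	4.47	58.3
T	4.35	61.8
V	4.12	62.2
W	4.66	57.5
Y	4.55	57.9
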