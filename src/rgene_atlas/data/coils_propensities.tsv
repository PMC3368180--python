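residue	propensity
A	1.297
C	0.918
D	0.191
E	3.520
F	0.285
G	0.045
H	0.386
I	2.597
K	3.985
L	3.167
M	2.240
N	0.891
P	0.055
Q	1.447
R	2.176
S	0.382
T	0.169
V	1.665
W	0.240
Y	1.417
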