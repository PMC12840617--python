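residue,hydrophobicity,hydrophilicity,mass,pk1,pk2,pi
A,1.8,-0.5,71.0788,2.34,9.69,6.01
C,2.5,-1.0,103.1388,1.96,10.28,5.07
D,-3.5,3.0,115.0886,1.88,9.60,2.77
E,-3.5,3.0,129.1155,2.19,9.67,3.22
F,2.8,-2.5,147.1766,1.83,9.13,5.48
G,-0.4,0.0,57.0519,2.34,9.60,5.97
H,-3.2,-0.5,137.1411,1.82,9.17,7.59
I,4.5,-1.8,113.1594,2.36,9.68,6.02
K,-3.9,3.0,128.1741,2.18,8.95,9.74
L,3.8,-1.8,113.1594,2.36,9.60,5.98
M,1.9,-1.3,131.1926,2.28,9.21,5.74
N,-3.5,0.2,114.1038,2.02,8.80,5.41
P,-1.6,0.0,97.1167,1.99,10.96,6.48
Q,-3.5,0.2,128.1307,2.17,9.13,5.65
R,-4.5,3.0,156.1875,2.17,9.04,10.76
S,-0.8,0.3,87.0782,2.21,9.15,5.68
T,-0.7,-0.4,101.1051,2.11,9.62,5.60
V,4.2,-1.5,99.1326,2.32,9.62,5.97
W,-0.9,-3.4,186.2132,2.38,9.39,5.89
Y,-1.3,-2.3,163.1760,2.20,9.11,5.66
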