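fatty_acid	D/E-0.61	D/E-1.46	D/E-2.75
C14:0	1.36	1.35	1.36
C16:0	13.68	14.02	13.96
C18:0	3.88	3.77	3.67
SFA_total	18.93	19.15	18.98
C16:1n-7	1.52	1.56	1.64
C18:1n-9	20.72	21.79	21.83
C18:1n-7	2.14	1.99	1.81
MUFA_total	24.37	25.35	25.27
C18:2n-6	21.18	21.19	21.15
C20:4n-6	3.69	3.15	2.91
n-6_PUFA_total	24.87	24.34	24.07
C18:3n-3	2.27	2.22	2.24
C20:5n-3	13.92	8.94	5.93
C22:5n-3	1.36	2.03	2.43
C22:6n-3	8.54	13.06	16.32
n-3_PUFA_total	26.10	26.25	26.92
n-3_LC-PUFA_total	23.83	24.03	24.68
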