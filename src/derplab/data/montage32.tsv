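label	x	y
Fp1	-0.31	0.95
Fpz	0.00	1.00
Fp2	0.31	0.95
F7	-0.81	0.59
F3	-0.35	0.52
Fz	0.00	0.50
F4	0.35	0.52
F8	0.81	0.59
FC5	-0.59	0.28
FC1	-0.20	0.26
FC2	0.20	0.26
FC6	0.59	0.28
T7	-1.00	0.00
C3	-0.50	0.00
Cz	0.00	0.00
C4	0.50	0.00
T8	1.00	0.00
TP9	-1.06	-0.33
CP5	-0.59	-0.28
CP1	-0.20	-0.26
CP2	0.20	-0.26
CP6	0.59	-0.28
TP10	1.06	-0.33
P7	-0.81	-0.59
P3	-0.35	-0.52
Pz	0.00	-0.50
P4	0.35	-0.52
P8	0.81	-0.59
POz	0.00	-0.75
O1	-0.31	-0.95
Oz	0.00	-1.00
O2	0.31	-0.95
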