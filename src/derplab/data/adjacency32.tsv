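a	b
Fp1	Fpz
Fpz	Fp2
F7	F3
F3	Fz
Fz	F4
F4	F8
FC5	FC1
FC1	FC2
FC2	FC6
T7	C3
C3	Cz
Cz	C4
C4	T8
CP5	CP1
CP1	CP2
CP2	CP6
P7	P3
P3	Pz
Pz	P4
P4	P8
O1	Oz
Oz	O2
Fp1	F7
Fp1	F3
Fpz	Fz
Fp2	F4
Fp2	F8
F7	FC5
F3	FC5
F3	FC1
Fz	FC1
Fz	FC2
F4	FC2
F4	FC6
F8	FC6
F7	T7
F8	T8
FC5	T7
FC5	C3
FC1	C3
FC1	Cz
FC2	Cz
FC2	C4
FC6	C4
FC6	T8
T7	TP9
T7	CP5
C3	CP5
C3	CP1
Cz	CP1
Cz	CP2
C4	CP2
C4	CP6
T8	CP6
T8	TP10
TP9	CP5
TP10	CP6
TP9	P7
CP5	P7
CP5	P3
CP1	P3
CP1	Pz
CP2	Pz
CP2	P4
CP6	P4
CP6	P8
TP10	P8
P7	O1
P3	O1
Pz	POz
P4	O2
P8	O2
POz	O1
POz	Oz
POz	O2
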