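name	start_ms	end_ms	polarity	electrodes
RP	80	250	positive	O1,Oz,O2,P3,Pz,P4
RN	150	350	negative	O1,Oz,O2,P3,Pz,P4
PP	250	700	positive	Pz,Cz,Fpz
FN	80	250	negative	C3,Cz,C4,F3,Fz,F4,Fp1,Fp2
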