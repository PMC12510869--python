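UVR.Sig	38-gene tumor-specific UV-response signature (published gene list)	ATF3	BTG3	FOS	FOSB	JUNB	NFKBIA	NR4A1	RHOB	SOD2	EPCAM	GGH	IGFBP2	CXCL2	BTG1	DNAJA1	DNAJB1	ALDOA	AP2S1	CDKN1C	ENO2	FEN1	HSPA2	OLFM1	PPIF	BTG2	ICAM1	SQSTM1	AMD1	ATP6V1F	BSG	CNP	CREG1	CYB5R1	MMP14	PPT1	RPN1	SELENOW	STIP1
Hub-UVR.Sig	7-gene hub subset selected by >=4-of-6 selector consensus	ATF3	ATP6V1F	BTG1	BTG3	ENO2	FOS	ICAM1
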