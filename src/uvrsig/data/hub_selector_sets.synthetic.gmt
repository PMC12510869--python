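lasso	synthetic per-selector gene lists; only the >=4-vote consensus outcome follows the published hub set	ATF3	ATP6V1F	BTG1	BTG3	ENO2	FOS	ICAM1	FOSB	JUNB	NFKBIA
rf_importance	synthetic selector output	ATF3	ATP6V1F	BTG1	BTG3	ENO2	FOS	ICAM1	SOD2	CXCL2
bagged_trees_importance	synthetic selector output	ATF3	ATP6V1F	BTG1	BTG3	ENO2	FOS	ICAM1	DNAJB1
lvq_importance	synthetic selector output	ATF3	ATP6V1F	BTG1	BTG3	ENO2	FOS	ICAM1	RHOB	FOSB
boruta	synthetic selector output	FOSB	JUNB	NR4A1
univariate_auc	synthetic selector output	CXCL2	SOD2	RHOB	BTG2
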