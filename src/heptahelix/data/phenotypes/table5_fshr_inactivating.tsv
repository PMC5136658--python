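mutation	bw	type	activity
I418S	2.60	Inactivating	FSH-induced cAMP abolished
A419T	2.61	Inactivating	FSH-induced cAMP abolished
P519T	ECL2	Inactivating	FSH-induced cAMP abolished
R573C	6.36	Inactivating	FSH-induced max. cAMP 30% WT
A575V	6.38	Inactivating	FSH-induced cAMP abolished
P587H	6.50	Inactivating	FSH-induced cAMP abolished
L601V	ECL3	Inactivating	FSH-induced max. cAMP 20% WT
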