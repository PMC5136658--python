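mutation	bw	type	activity
I374T	1.47	Inactivating	
T392I	ICL1	Inactivating	
C543R	5.55	Inactivating	LH-induced cAMP abolished
A593P	6.59	Inactivating	LH-induced cAMP abolished
S616Y	7.46	Inactivating	LH-induced EC50 20-fold WT
I625K	7.55	Inactivating	LH-induced EC50 20-fold WT
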