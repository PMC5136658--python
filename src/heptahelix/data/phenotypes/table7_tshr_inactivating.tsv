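mutation	bw	type	activity
V424I	1.42	Silencing	cAMP 0.3-fold WT
D460A	2.50	Silencing	cAMP 0.28-fold WT
D460N	2.50	Silencing	cAMP 0.18-fold WT
L467V	2.57	Silencing	cAMP 0.1-fold WT
W488R	ECL1	Inactivating	TSH binding abolished
V502A	3.33	Silencing	cAMP 0.0-fold WT
M527T	ICL2	Inactivating	TSH induced max. cAMP 30% WT
Y582A	5.39	Silencing	cAMP 0.2-fold WT
Y582F	5.39	Silencing	cAMP 0.4-fold WT
A593P	5.50	Silencing	cAMP 0.19-fold WT
A593V	5.50	Silencing	cAMP 0.33-fold WT
F594I	5.51	Silencing	cAMP 0.13-fold WT
R625A	6.36	Silencing	cAMP 0.11-fold WT
F634I	6.45	Silencing	cAMP 0.13-fold WT
A638V	6.49	Inactivating	TSH induced EC50 7.85-fold WT
F642I	6.53	Inactivating	TSH induced EC50 8.21-fold WT
Y643A	6.54	Silencing	cAMP 0.2-fold WT
A644V	6.55	Inactivating	TSH induced EC50 8.88-fold WT
L665V	7.40	Silencing	cAMP 0.3-fold WT
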