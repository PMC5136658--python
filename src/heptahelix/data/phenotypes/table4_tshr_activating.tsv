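mutation	bw	type	activity
V421I	1.39	CAM	cAMP 2.1-fold WT
Y466A	2.56	CAM	cAMP 2.8-fold WT
I486N	ECL1	CAM	cAMP 4-fold WT
T501A	3.32	CAM	cAMP 3.4-fold WT
L512R	3.43	CAM	cAMP 3.2-fold WT
A593G	5.50	CAM	cAMP 2.13-fold WT
L629F	6.40	CAM	cAMP 2.2-fold WT
F631I	6.42	CAM	cAMP 3.7-fold WT
T632A	6.43	CAM	cAMP 9.7-fold WT
D633A	6.44	CAM	cAMP 13.6-fold WT
D633E	6.44	CAM	cAMP 3.3-fold WT
C636R	6.47	CAM	cAMP 7.7-fold WT
C636S	6.47	CAM	cAMP 5.5-fold WT
M637C	6.48	CAM	cAMP 2.4-fold WT
M637W	6.48	CAM	cAMP 4.8-fold WT
P639G	6.50	CAM	cAMP 4.9-fold WT
P639A	6.50	CAM	cAMP 4.8-fold WT
P639S	6.50	CAM	cAMP 4.8-fold WT
S641A	6.52	CAM	cAMP 3.1-fold WT
Y643F	6.54	CAM	cAMP 2.1-fold WT
L645V	6.56	CAM	cAMP 2.1-fold WT
L665F	7.40	CAM	cAMP 3-fold WT
N674D	7.49	CAM	cAMP 11.3-fold WT
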