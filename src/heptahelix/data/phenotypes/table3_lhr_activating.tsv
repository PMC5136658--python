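mutation	bw	type	activity
A373V	1.46	CAM	cAMP 7.5-fold WT
M398T	2.43	CAM	cAMP 25-fold WT
L457R	3.43	CAM	cAMP 10-fold WT
I542L	5.55	CAM	cAMP 7-fold WT
D564G	6.30	CAM	cAMP 5-fold WT
A568V	6.34	CAM	cAMP 4-fold WT
M571I	6.37	Activating	
A572V	6.38	Activating	
I575L	6.41	CAM	cAMP 20-fold WT
T577I	6.43	Activating	
D578G	6.44	CAM	cAMP 6.6-fold WT
D578Y	6.44	CAM	cAMP 13-fold WT
D578E	6.44	CAM	cAMP 4.3-fold WT
D578H	6.44	CAM	cAMP 14.4-fold WT
D578Q	6.44	CAM	cAMP 10.2-fold WT
C581R	6.47	CAM	cAMP 5-fold WT
N615R	7.45	CAM	cAMP 2.6-fold WT
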