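mutation	bw	type	activity
M401T	2.43	CAM	cAMP 3.60-fold WT
T449A	3.32	CAM	cAMP 2.5-fold WT
L460R	3.43	CAM	cAMP 5-fold WT
I545T	5.46	CAM	cAMP 2.3-fold WT
I545L	5.46	CAM	cAMP 4.53-fold WT
D567N	6.30	CAM	cAMP 3-fold WT
M574I	6.37	CAM	cAMP 2.19-fold WT
A575V	6.38	CAM	cAMP 2.95-fold WT
I578L	6.41	CAM	cAMP 2.49-fold WT
T580I	6.43	CAM	cAMP 5.41-fold WT
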