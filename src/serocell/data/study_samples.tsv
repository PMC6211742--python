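sample_id	patient_id	site	grade	n_cells
BN1-P	BN1	primary	benign	223
HG1-P	HG1	primary	HGSOC	252
HG1-M	HG1	metastatic	HGSOC	325
HG2F-P	HG2F	primary	HGSOC-F	260
HG2F-M	HG2F	metastatic	HGSOC-F	259
HG3-P	HG3	primary	HGSOC	213
HG3-M	HG3	metastatic	HGSOC	312
HG4-P	HG4	primary	HGSOC	174
HG5-P	HG5	primary	HGSOC	56
LG1-P	LG1	primary	LGSOC	194
NM1	LG1	normal	normal	344
LG2-P	LG2	primary	LGSOC	130
LG2-M	LG2	metastatic	LGSOC	125
PN1-P	PN1	primary	peritoneal	44
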