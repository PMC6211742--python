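patient_id	age	neoplasm	stage
BN1	56	benign	
HG1	70	HGSOC	IIIA
HG2F	67	HGSOC-F	IIIB
HG3	66	HGSOC	IIIC
HG4	54	HGSOC	IIIA
HG5	69	HGSOC	IIIC
LG1	67	LGSOC	IA
LG2	58	LGSOC	IIIC
PN1	55	peritoneal	IV
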