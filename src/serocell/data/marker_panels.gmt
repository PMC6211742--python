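epithelial	epithelial/mesothelial markers	EPCAM	KRT8	KRT18	KRT19
lymphocyte	T and B cell markers	PTPRC	CD3E	CD19	MS4A1
endothelial	endothelial markers	PECAM1	CD34
fibroblast	fibroblast markers	ACTA2	DCN	ACTB
stromal	stromal markers	THY1	ENG	VIM	CD44
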