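comparison	gene	avg_log2fc	pct_in	pct_out	p_adj
tumor_epithelial_vs_rest	WFDC2	2.373	0.772	0.108	0
tumor_epithelial_vs_rest	CLDN4	2.271	0.615	0.034	0
tumor_epithelial_vs_rest	FXYD3	2.202	0.537	0.025	0
tumor_epithelial_vs_rest	CD24	2.111	0.647	0.071	0
tumor_epithelial_vs_rest	ELF3	2.061	0.636	0.061	0
tumor_epithelial_vs_rest	CLDN3	2.045	0.623	0.031	0
tumor_epithelial_vs_rest	MUC1	1.995	0.648	0.08	0
tumor_epithelial_vs_rest	SPINT2	1.831	0.638	0.09	0
tumor_epithelial_vs_rest	KRT8	1.767	0.664	0.086	0
tumor_epithelial_vs_rest	SLPI	1.681	0.646	0.074	0
tumor_epithelial_vs_rest	KRT18	1.640	0.671	0.134	0
tumor_epithelial_vs_rest	KRT19	1.590	0.613	0.098	4.7E-297
hgsocf_epithelial_vs_other_epithelial	TPPP3	3.377	0.885	0.083	1.1E-279
hgsocf_epithelial_vs_other_epithelial	C20orf85	3.177	0.723	0.007	4.8E-299
hgsocf_epithelial_vs_other_epithelial	FOXJ1	2.545	0.857	0.257	6E-159
hgsocf_epithelial_vs_other_epithelial	RSPH1	2.455	0.615	0.033	1.2E-199
hgsocf_epithelial_vs_other_epithelial	ZMYND10	2.285	0.569	0.02	4.7E-198
hgsocf_epithelial_vs_other_epithelial	CAPS	2.197	0.731	0.218	2.3E-118
hg3_epithelial_vs_other_epithelial	SST	3.771	0.547	0.022	4.6E-181
hg3_epithelial_vs_other_epithelial	TFF3	2.665	0.607	0.054	1.4E-176
hg3_epithelial_vs_other_epithelial	PIGR	2.628	0.661	0.017	7.3E-243
hg3_epithelial_vs_other_epithelial	GPNMB	2.010	0.65	0.021	4.7E-227
hg3_epithelial_vs_other_epithelial	XBP1	1.824	0.768	0.173	6E-179
hg3_epithelial_vs_other_epithelial	LYNX1	1.792	0.553	0.034	1.7E-169
hg3_epithelial_vs_other_epithelial	AGR2	1.727	0.603	0.055	2.5E-170
hg3_epithelial_vs_other_epithelial	DDIT4	1.639	0.846	0.272	2E-162
hg3_epithelial_vs_other_epithelial	CXCL17	1.575	0.608	0.055	2.6E-173
hg3_epithelial_vs_other_epithelial	KIAA1324	1.564	0.561	0.025	1.2E-180
hg3_epithelial_vs_other_epithelial	NNMT	1.522	0.654	0.085	1.1E-164
hg3_epithelial_vs_other_epithelial	STARD10	1.392	0.585	0.079	6.5E-142
tumor_stroma_vs_normal	COL1A2	3.416	0.746	0.139	2.8E-84
tumor_stroma_vs_normal	COL3A1	3.093	0.702	0.097	1.88E-77
tumor_stroma_vs_normal	COL1A1	3.481	0.733	0.231	1.17E-71
tumor_stroma_vs_normal	COL6A3	1.985	0.567	0.083	1.09E-50
tumor_stroma_vs_normal	COL5A1	1.825	0.509	0.05	7.49E-46
tumor_stroma_vs_normal	COL5A2	1.634	0.488	0.028	4.77E-45
tumor_stroma_vs_normal	COL4A1	2.313	0.542	0.094	4.18E-42
tumor_stroma_vs_normal	COL4A2	1.871	0.554	0.122	3.91E-39
tumor_stroma_vs_normal	COL6A1	1.154	0.676	0.317	4.17E-30
tumor_stroma_vs_normal	MMP2	1.152	0.377	0.047	1.27E-26
tumor_stroma_vs_normal	TIMP1	1.457	0.718	0.425	2.08E-25
tumor_stroma_vs_normal	MMP11	1.185	0.189	0.008	1.03E-12
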