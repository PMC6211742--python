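group	level	differentiated	immunoreactive	mesenchymal	proliferative
BN1-P	sample	3.246	0.712	1.062	0.189
HG1-P	sample	1.144	0.613	1.476	0.544
HG1-M	sample	1.113	0.887	2.299	0.347
HG2F-P	sample	1.942	0.240	0.657	0.608
HG2F-M	sample	1.351	1.231	0.574	0.345
HG3-P	sample	2.062	1.037	1.426	0.464
HG3-M	sample	1.498	1.681	0.956	0.350
HG4-P	sample	1.523	2.527	0.732	0.366
HG4-M	sample	1.934	0.228	0.834	0.292
LG1-P	sample	0.999	0.590	1.902	0.395
LG1-N	sample	0.871	0.124	1.973	0.416
LG2-P	sample	3.604	0.514	1.449	0.284
LG2-M	sample	2.968	0.684	3.831	0.236
PN1-P	sample	1.594	0.291	1.635	0.690
B-cells	cluster	0.194	1.496	0.318	0.442
benign epithelial	cluster	4.216	0.621	0.654	0.180
cancer stromal cells	cluster	0.447	0.142	4.559	0.355
CD4 T-cells	cluster	1.848	1.245	0.353	0.331
CD8 T-cells	cluster	1.105	1.594	0.568	0.349
endothelial progenitor	cluster	1.112	0.208	2.012	0.481
HGSOC-F tumor epithelial	cluster	2.946	0.202	0.347	0.424
LGSOC epithelial	cluster	3.808	0.227	0.488	0.304
metastatic fibroblasts	cluster	1.304	0.270	5.074	0.389
metastatic myeloid lineage	cluster	1.129	3.931	1.088	0.261
normal fibroblasts	cluster	0.553	0.159	1.429	0.616
normal stromal cells	cluster	0.937	0.076	2.439	0.293
HGSOC epithelial	cluster	1.691	0.226	0.413	0.569
primary fibroblasts	cluster	0.493	0.174	3.337	0.582
primary myeloid lineage	cluster	0.744	3.732	1.354	0.272
HG3 tumor epithelial	cluster	2.753	0.822	0.711	0.491
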