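rxn_id	enzyme	ec	route	equation
R00238	acetyl-CoA C-acetyltransferase	2.3.1.9	mevalonate	[c]: C00024 --> C00332
R01978	hydroxymethylglutaryl-CoA synthase	2.3.3.10	mevalonate	[c]: C00332 + C00024 --> C00356
R02082	3-hydroxy-3-methylglutaryl-CoA reductase	1.1.1.34	mevalonate	[c]: C00356 --> C00418
R02245	mevalonate kinase	2.7.1.36	mevalonate	[c]: C00418 --> C01107
R03245	phosphomevalonate kinase	2.7.4.2	mevalonate	[c]: C01107 --> C01143
R01121	diphosphomevalonate decarboxylase	4.1.1.33	mevalonate	[c]: C01143 --> C00129
R01123	isopentenyl-diphosphate delta-isomerase	5.3.3.2	mevalonate	[c]: C00129 --> C00235
R05636	DOXP synthase (Dxs)	2.2.1.7	non_mevalonate	[c]: C00118 + C00022 --> C11437
R05688	DOXP reductase (Dxr)	1.1.1.267	non_mevalonate	[c]: C11437 --> C11434
R05633	MEP synthase (IspD)	2.7.7.60	non_mevalonate	[c]: C11434 --> C11435
R05634	CDP-ME kinase (IspE)	2.7.1.148	non_mevalonate	[c]: C11435 --> C11436
R05637	CDP-MEP synthase (IspF)	4.6.1.12	non_mevalonate	[c]: C11436 --> C11453
R08689	HMB-PP synthase (IspG)	1.17.4.3	non_mevalonate	[c]: C11453 --> C11811
R05884	HMB-PP reductase (IspH)	1.17.7.1	non_mevalonate	[c]: C11811 --> C00129
R08209	HMB-PP reductase (IspH)	1.17.1.2	non_mevalonate	[c]: C11811 --> C00129
R01123	IPP delta-isomerase	5.3.3.2	non_mevalonate	[c]: C00129 --> C00235
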