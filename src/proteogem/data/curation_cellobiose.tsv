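rxn_id	equation	lb	ub	ec	genes	subsystem	evidence_note
CELB_HYDROLYSIS	[c]: C00185 + C00001 --> 2 C00031	0	1000	3.2.1.21	Tfu_0937	Starch and Sucrose Metabolism	beta-glucosidase expressed on cellobiose-grown cells; canonical hydrolysis stoichiometry
EX_C00185	[c]: C00185 <-->	-1000	1000			Exchange	cellobiose supplied as the sole carbon source in the growth medium
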