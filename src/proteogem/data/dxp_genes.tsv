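locus	ncbi_gene_id	strand	start_pos	end_pos	nt_length
Tfu_1917	3580825	complementary	2242018	2243931	1914
Tfu_0747	3578952	forward	880259	881473	1215
Tfu_0407	3580006	forward	458401	459324	924
Tfu_2906	3581392	complementary	3421460	3421924	465
Tfu_0749	3578954	forward	883104	884261	1158
Tfu_0471	3579613	forward	532475	533476	1002
Tfu_3076	3580076	forward	3598495	3599487	993
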