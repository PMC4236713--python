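category	pathway	reference_count	tfu_v1_count	tfu_v1_pct	tfu_v2_count	tfu_v2_pct	tfu_v3_count	tfu_v3_pct
carbohydrate	Glycolysis/Gluconeogenesis	45	28	62	22	49	15	33
carbohydrate	Citrate Cycle (TCA Cycle)	22	15	68	15	68	13	59
carbohydrate	Pentose Phosphate Pathway	40	20	50	15	38	13	33
carbohydrate	Pentose and Glucuronate Interconversions	61	10	16	8	13	6	10
carbohydrate	Fructose and Mannose Metabolism	65	14	22	14	22	5	8
carbohydrate	Galactose Metabolism	38	12	32	13	34	8	21
carbohydrate	Starch and Sucrose Metabolism	74	14	19	14	19	12	16
carbohydrate	Amino Sugar and Nucleotide Metabolism	108	25	23	21	19	15	14
carbohydrate	Pyruvate Metabolism	64	26	41	17	27	15	23
carbohydrate	Glyoxylate and Dicarboxylate Metabolism	66	12	18	11	17	7	11
carbohydrate	Propanoate Metabolism	47	17	36	14	30	12	26
carbohydrate	Butanoate Metabolism	50	17	34	12	24	7	14
carbohydrate	C-5 Branched Dibasic Acid Metabolism	18	3	17	3	17	1	6
carbohydrate	Inositol Phosphate Metabolism	43	4	9	5	12	4	9
amino_acid	Ala, Asp and Glu Metabolism	43	21	49	19	44	18	42
amino_acid	Gly, Ser and Thr Metabolism	63	11	17	13	21	9	14
amino_acid	Cys and Met Metabolism	66	8	12	3	5	3	5
amino_acid	Val, Leu and Ile Degradation	35	18	51	13	37	16	46
amino_acid	Val, Leu and Ile Biosynthesis	14	10	71	10	71	7	50
amino_acid	Lys Biosynthesis	30	13	43	10	33	8	27
amino_acid	Lys Degradation	54	7	13	8	15	7	13
amino_acid	Arg and Pro Metabolism	104	32	31	26	25	22	21
amino_acid	His Metabolism	37	12	32	13	35	10	27
amino_acid	Tyr Metabolism	66	11	17	8	12	9	14
amino_acid	Phe Metabolism	70	11	16	9	13	9	13
amino_acid	Trp Metabolism	69	14	20	14	20	9	13
amino_acid	Phe, Tyr and Trp Biosynthesis	37	26	70	16	43	16	43
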