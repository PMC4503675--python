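gene_id	age_class	orf_length_codons	top_tissue	tissue_breadth	peptide_count
ENSG00000178803	H	159	Kidney	4	7
ENSG00000204626	H	163	Cerebellum	7	8
ENSG00000145063	H	174	Brain	1	12
ENSG00000172927	H	313	Breast	3	14
ENSG00000177822	H-C	148	Adipose	4	7
ENSG00000179522	H-C	230	Prostate	5	9
ENSG00000215071	H-C	121	Testes	14	2
ENSG00000182457	H-C	135	Ovary	17	3
ENSG00000174407	H-C-O	99	Heart	5	6
ENSG00000203930	H	103	Cerebellum	2	2
ENSG00000204091	H-C-O	100	Testes	3	3
ENSG00000204666	H-C	122	Brain	2	8
ENSG00000204674	H-C	123	Cerebellum	13	10
ENSG00000212736	H-C-O	115	Adrenal	16	8
ENSG00000167747	H-C-O	117	Testes	17	11
ENSG00000214112	H-C-O	72	Heart	2	3
ENSG00000214130	H-C	149	Heart	2	5
ENSG00000118267	H	423	Colon	17	33
ENSG00000215458	H	302	Blood	5	18
ENSG00000215494	H	152	Breast	1	12
ENSG00000215848	H	161	Brain	3	6
ENSG00000221953	H	237	Brain	1	15
ENSG00000221891	H-C-O	157	Testes	4	13
ENSG00000221899	H	166	Lymph_node	10	17
ENSG00000205056	H	121	Blood	1	2
ENSG00000198547	H	194	Brain	2	13
ENSG00000136242	H	128	Testes	16	4
ENSG00000162968	H	151	Brain	3	4
ENSG00000175913	H	147	Cerebellum	2	9
ENSG00000176833	H	126	Testes	1	7
ENSG00000176911	H	134	Breast	1	5
ENSG00000180838	H	131	Prostate	3	4
ENSG00000187488	H	221	Testes	17	2
ENSG00000196273	H	105	Testes	1	10
ENSG00000197916	H	129	Adipose	16	3
ENSG00000204079	H	141	Adrenal	1	6
ENSG00000204292	H	150	Testes	1	2
ENSG00000204380	H	155	Cerebellum	10	6
ENSG00000205373	H	219	Testes	13	4
ENSG00000205557	H	149	Cerebellum	3	2
ENSG00000205965	H	175	Kidney	2	4
ENSG00000206028	H	164	Brain	5	8
ENSG00000206096	H	127	Testes	4	5
ENSG00000206110	H	129	Brain	1	8
ENSG00000206113	H	213	Testes	1	13
ENSG00000212693	H	131	Thyroid	6	3
ENSG00000214780	H	195	Brain	1	3
ENSG00000218478	H	158	Kidney	16	2
ENSG00000223857	H	131	Brain	12	7
ENSG00000224013	H	164	Cerebellum	6	8
ENSG00000225021	H	144	Liver	7	4
ENSG00000225860	H	175	Brain	1	8
ENSG00000225917	H	269	Brain	15	15
ENSG00000230294	H	119	Testes	1	8
ENSG00000235766	H	142	Lung	12	4
ENSG00000236314	H	156	Testes	17	10
ENSG00000260456	H-C-G	158	Testes	15	6
ENSG00000149443	H-C	151	Testes	1	11
ENSG00000167159	H-C-O	157	Cerebellum	7	1
ENSG00000008517	H-C	188	Kidney	17	3
ENSG00000183250	H-C-O	204	Brain	7	7
ENSG00000244291	H-C	216	Testes	17	9
ENSG00000205913	H-C	107	Brain	3	4
ENSG00000221990	H-C-G-O	119	Testes	13	15
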