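locus_tag	sigma	minus35	minus10	spacing_35_10	dist_10_to_start	rbs	rbs_spacing
RHOM_15820	28	taaa	gcgatat	9	261	AGGAGA	8
RHOM_00820	28	taaa	tcgatat	17	47	AAGAGG	9
RHOM_00665	28	taaa	ccgatat	16	136	AGGAGG	8
ROSINTL182_05247	28	taga	ccgatat	15	78	AGAAGG	9
ROSINTL182_08635	-	taaa	-	-	-	CGGAGG	14
ROSINTL182_05608	28	taaa	tcgatat	17	47	AAGAGG	9
ROSINTL182_05608	43	tttaca	cataaa	9	24	AAGAGG	9
ROSINTL182_07256	28	taaa	ccgatat	16	149	AGGAGG	9
ROSINTL182_09568	-	taaa	-	-	-	-	-
ROSEINA2194_00754	28	taag	acgatat	17	34	AGAAGG	10
ROSEINA2194_01954	28	taat	ccgataa	27	193	AGGAGA	6
ROSEINA2194_00384	28	taaa	ccgatat	16	146	AGGAGG	8
ROSEINA2194_00384	43	attaca	aataat	12	0	AGGAGG	8
ROSEINA2194_00549	43	tttaca	aataat	18	142	CGGAGG	8
ROSEINA2194_01473	-	-	-	-	-	AGGAGG	8
ROSEINA2194_02155	28	tgaa	gcgataa	23	375	AGGAGG	8
EUBELI_00422	-	taaa	-	-	-	CGGAGG	8
EUBELI_00241	28	taaa	ccgatat	16	93	AGGAGG	8
EUBELI_00264	28	ttaa	ccgataa	16	92	AGGAGG	8
EUBELI_00264	43	taaaca	aataat	13	52	AGGAGG	8
EUR_28730	28	taaa	tcgatat	17	69	AGGAAA	9
EUR_04790	43	tttcca	cataat	9	32	AGGAGG	8
EUR_14430	-	-	-	-	-	TGGAGG	8
EUR_04300	43	tttcca	cataat	9	33	AGGAGG	8
EUR_14450	43	tttacc	aataat	12	22	TGGAGG	8
ERE_01930	28	taaa	tcgatat	17	69	AGGAAA	9
ERE_14590	-	-	-	-	-	AGGAGG	8
ERE_14720	-	-	-	-	-	AGGAGG	8
ERE_12290	-	-	-	-	-	-	-
ES1_07000	43	tttaca	tataaa	10	258	AGGAGG	17
ES1_07000	28	taaa	ccgatat	17	192	AGGAGG	17
EUBSIR_02119	43	tttaca	caaaat	11	258	AGGAGG	17
EUBSIR_02119	28	taaa	ccgatat	17	192	AGGAGG	17
EUS_23890	43	tttaca	tataaa	9	258	AGGAGG	17
EUS_23890	28	taaa	ccgatat	17	192	AGGAGG	17
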