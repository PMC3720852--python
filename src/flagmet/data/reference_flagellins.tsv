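species	locus_tag	clade	size_aa	size_kda	nterm10
R. hominis L1-83	RHOM_15820	a	506	54.48	MRINYNVSAS
R. hominis L1-83	RHOM_00820	d	275	30.62	MVVNHNMAAI
R. hominis L1-83	RHOM_00665	e	270	28.60	MVVQHNLTAM
R. intestinalis L1-82	ROSINTL182_05247	a	486	51.90	MRINYNVSAA
R. intestinalis L1-82	ROSINTL182_08635	c	539	56.13	MVVQHNMSAM
R. intestinalis L1-82	ROSINTL182_05608	d	275	30.55	MVVNHNMALI
R. intestinalis L1-82	ROSINTL182_07256	e	272	29.04	MVVQHNMTAM
R. intestinalis L1-82	ROSINTL182_09568	-	61	6.97	MTLIQNRLEY
R. inulinivorans A2-194	ROSEINA2194_00754	a	493	52.52	MRINNNMSAV
R. inulinivorans A2-194	ROSEINA2194_01954	d	426	47.24	MQVLAHNLAA
R. inulinivorans A2-194	ROSEINA2194_00384	e	270	28.77	MVVQHNMTAA
R. inulinivorans A2-194	ROSEINA2194_00549	f	389	42.06	MVVQHNMQAM
R. inulinivorans A2-194	ROSEINA2194_01473	f	392	42.26	MVVQHNLQAM
R. inulinivorans A2-194	ROSEINA2194_02155	f	466	49.23	MVVQHNMQAM
E. eligens ATCC27750	EUBELI_00422	c	497	52.32	MVVQHNMAAM
E. eligens ATCC27750	EUBELI_00241	e	270	28.93	MVVQHNLSAM
E. eligens ATCC27750	EUBELI_00264	e	270	29.12	MVVQHNLSAM
E. rectale A1-86	EUR_28730	a	476	50.78	MKINRNMSAV
E. rectale A1-86	EUR_04790	f	504	53.41	MVVQHNMQAA
E. rectale A1-86	EUR_14430	f	480	50.22	MVVQHNMQAA
E. rectale A1-86	EUR_04300	f	476	50.10	MVVQHNMQAA
E. rectale A1-86	EUR_14450	f	455	47.51	MVVQHNMQAA
E. rectale M104/1	ERE_01930	a	476	50.77	MKINRNMSAV
E. rectale M104/1	ERE_14590	f	458	48.29	MVVQHNMQAM
E. rectale M104/1	ERE_14720	f	504	53.41	MVVQHNMQAA
E. rectale M104/1	ERE_12290	-	446	46.82	YRINRAADDA
E. siraeum V10Sc8a	ES1_07000	b	530	55.81	MVVQHNLNAI
E. siraeum DSM15702	EUBSIR_02119	b	539	56.24	MVVQHNLNAI
E. siraeum 70/3	EUS_23890	b	547	56.97	MVVQHNLNAI
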