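snp_id	chrom	pos	effect_allele	other_allele	eaf	beta	se	p	n	f_published
rs113740320	1	29179467	T	G	0.06699	0.2367	0.0497	1.90e-06	3301	22.66
rs149451734	2	3955107	A	G	0.02162	-0.4357	0.0944	3.89e-06	3301	21.28
rs17762054	2	163010686	C	T	0.02211	0.3993	0.0843	2.18e-06	3301	22.42
rs10004661	4	182498876	A	C	0.34907	-0.1198	0.0259	3.63e-06	3301	21.38
rs1380012	4	179052399	C	T	0.75385	0.1407	0.029	1.23e-06	3301	23.52
rs7757428	6	91502332	G	A	0.32895	0.1216	0.0263	3.63e-06	3301	21.36
rs1044043	6	32793981	C	A	0.78396	-0.137	0.0299	4.67e-06	3301	20.98
rs62521900	8	141901195	T	G	0.01852	-0.4771	0.1016	2.63e-06	3301	22.03
rs13252141	8	11128104	T	C	0.19011	0.1593	0.0323	7.76e-07	3301	24.30
rs7873013	9	122676273	T	G	0.6277	0.1299	0.0258	4.67e-07	3301	25.33
rs7142713	14	28313517	A	G	0.27272	-0.1313	0.0281	2.95e-06	3301	21.81
rs3742848	14	71191423	T	C	0.5992	-0.1205	0.0252	1.69e-06	3301	22.85
rs73469695	15	98631091	C	T	0.0481	0.2749	0.0589	3.01e-06	3301	21.76
rs145701180	16	31725945	G	A	0.02487	0.4228	0.0896	2.34e-06	3301	22.25
rs58124292	16	81890435	A	G	0.20348	-0.1517	0.0318	1.81e-06	3301	22.74
rs59902361	20	38334734	A	G	0.02218	-0.391	0.0856	4.89e-06	3301	20.85
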