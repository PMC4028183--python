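locus_id	snp	risk_allele	other_allele	hr_per_allele	weight	risk_allele_frequency
ADAMTS9	rs6795735	C	T	1.01	0.009950	0.7230
ADCY5	rs11717195	T	C	1.11	0.104360	0.2933
ANK1	rs516946	C	T	1.07	0.067659	0.7020
ANKRD55	rs459193	G	A	1.05	0.048790	0.3250
ARAP1	rs1552224	A	G	1.13	0.122218	0.7750
BCAR1	rs7202877	T	C	1.14	0.131028	0.3565
BCL11A	rs243088	T	C	1.06	0.058269	0.7805
CCND2	rs11063069	G	A	1.11	0.104360	0.2785
CDC123_CAMK1D	rs11257655	T	C	1.05	0.048790	0.7805
CDKAL1	rs7756992	G	A	1.15	0.139762	0.2763
CDKN2A_B	rs10811661	T	C	1.14	0.131028	0.6938
CILP2	rs10401969	C	T	1.10	0.095310	0.2549
DGKB	rs17168486	T	C	1.08	0.076961	0.7828
FTO	rs9936385	C	T	1.10	0.095310	0.2931
GCK	rs10278336	A	G	1.02	0.019803	0.7536
GCKR	rs780094	C	T	1.03	0.029559	0.3659
GIPR	rs8108269	G	A	1.06	0.058269	0.7481
GRB14	rs13389219	C	T	1.08	0.076961	0.3333
HHEX_IDE	rs1111875	C	T	1.15	0.139762	0.7771
HMG20A	rs7177055	A	G	1.09	0.086178	0.2684
HMGA2	rs2261181	T	C	1.17	0.157004	0.7666
HNF1A	rs12427353	G	A	1.11	0.104360	0.3193
HNF1B	rs11651052	A	G	1.06	0.058269	0.7904
IGF2BP2	rs4402960	T	C	1.15	0.139762	0.3539
IRS1	rs2943640	C	T	1.10	0.095310	0.7350
JAZF1	rs849135	G	A	1.07	0.067659	0.2648
KCNJ11	rs5215	C	T	1.07	0.067659	0.7625
KCNQ1	rs163184	G	A	1.10	0.095310	0.3625
KLF14	rs13233731	G	A	1.03	0.029559	0.7329
KLHDC5	rs10842994	C	T	1.13	0.122218	0.2562
MC4R	rs12970134	A	G	1.02	0.019803	0.7541
MTNR1B	rs10830963	G	A	1.10	0.095310	0.2894
NOTCH2	rs10923931	T	C	1.02	0.019803	0.7505
PPARG	rs1801282	C	T	1.08	0.076961	0.2861
PRC1	rs12899811	G	A	1.05	0.048790	0.7105
PROX1	rs2075423	G	A	1.03	0.029559	0.2666
SLC30A8	rs3802177	G	A	1.14	0.131028	0.7147
SPRY2	rs1359790	G	A	1.04	0.039221	0.2600
TCF7L2	rs7903146	T	C	1.33	0.285179	0.7752
THADA	rs10203174	C	T	1.15	0.139762	0.2939
TLE1	rs2796441	G	A	1.06	0.058269	0.7349
TLE4	rs17791513	A	G	1.08	0.076961	0.3497
TP53INP1	rs7845219	T	C	1.05	0.048790	0.7228
TSPAN8_LGR5	rs7955901	C	T	1.03	0.029559	0.3023
UBE2E2	rs1496653	A	G	1.10	0.095310	0.7843
WFS1	rs4458523	G	A	1.09	0.086178	0.2924
ZBED3	rs6878122	G	A	1.07	0.067659	0.7294
ZFAND6	rs11634397	G	A	1.04	0.039221	0.2886
ZMIZ1	rs12571751	A	G	1.09	0.086178	0.7892
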