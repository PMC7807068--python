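variable	minimal_depth	vimp	cindex	error	drop_error
SALL1_rs10521222	1.9902	0.0554	0.6018	0.3982	0.1018
oc_years	2.0644	0.0541	0.7001	0.2999	0.0983
HLA-DQA1_rs9271608	2.7866	0.0413	0.7878	0.2122	0.0878
DUSP1_rs17658229	3.5022	0.0104	0.7990	0.2010	0.0111
bmi	3.5034	0.0113	0.8180	0.1820	0.0190
hip	3.5554	0.0073	0.8180	0.1820	-1.00e-05
alcohol	3.5568	0.0049	0.8187	0.1813	7.00e-04
waist	3.5862	0.0075	0.8169	0.1831	-0.0018
APOC1_rs4420638	3.5908	0.0167	0.8242	0.1758	0.0073
TRAIP_rs2352975	3.5954	0.0146	0.8359	0.1641	0.0118
age_menopause	3.7836	0.0024	0.8392	0.1608	0.0033
ep_years	3.8872	0.0095	0.8539	0.1461	0.0147
cigarettes_per_day	4.0458	0.0015	0.8539	0.1461	-9.00e-05
depressive_symptom	4.2520	0.0015	0.8525	0.1475	-0.0014
whr	4.3148	0.0022	0.8503	0.1497	-0.0022
income	4.3646	0.0011	0.8479	0.1521	-0.0024
APOC1_rs5117	4.4182	0.0050	0.8494	0.1506	0.0016
IRF1_rs4705952	4.4548	0.0046	0.8500	0.1500	0.0005
protein_pct	4.6538	0.0007	0.8486	0.1514	-0.0014
TOMM40_rs157581	4.7930	0.0037	0.8499	0.1501	0.0013
METAP2_rs11108056	4.8540	0.0017	0.8495	0.1505	-0.0004
BCL7B_rs13233571	5.0108	-0.0001	0.8487	0.1513	-0.0008
CENPW_rs1490384	5.0488	0.0004	0.8458	0.1542	-0.0029
IKZF2_rs1441169	5.1550	0.0002	0.8439	0.1561	-0.0019
HNF4A_rs1800961	5.1846	0.0051	0.8455	0.1545	0.0016
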