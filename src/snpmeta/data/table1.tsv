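study_id	author	year	snp	ethnicity	source	case_rr	case_rw	case_ww	control_rr	control_rw	control_ww	case_total	control_total	reported_hwe_p
hu2014	Hu	2014	rs2735839	Asian	PB	25	68	15	44	108	90	108	242	0.25
wang2013	Wang	2013	rs2735839	Asian	PB	102	126	57	98	144	38	285	280	0.19
eeles2008_rs2735839	Eeles	2008	rs2735839	Caucasian	PB	35	406	1410	103	591	1193	1851	1887	0.01
parikh2011_rs2735839	Parikh	2011	rs2735839	Caucasian	PB	260	299	2591	261	288	2431	3150	2980	<0.01
cicek2005	Cicek	2005	rs266882	Caucasian	FB	119	196	124	119	236	124	439	479	0.75
lai2007	Lai	2007	rs266882	Caucasian	PB	35	111	63	71	107	45	209	223	0.68
penney2011_rs266882	Penney	2011	rs266882	Caucasian	PB	255	483	228	346	622	311	966	1279	0.34
penney2011_rs1058205	Penney	2011	rs1058205	Caucasian	PB	14	176	706	28	269	868	896	1165	0.19
chen2017	Chen	2017	rs1058205	Asian	HB	4	55	209	7	89	202	268	298	0.44
eeles2008_rs1058205	Eeles	2008	rs1058205	Caucasian	PB	54	490	1306	136	674	1077	1850	1887	0.03
stegeman2015	Stegeman	2015	rs1058205	Caucasian	PB	446	5798	161057	670	6476	15177	22301	22320	0.53
parikh2011_rs1058205	Parikh	2011	rs1058205	Caucasian	PB	373	329	2813	410	298	2621	3515	3329	<0.01
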