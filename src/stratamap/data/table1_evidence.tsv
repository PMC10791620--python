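# Per-gene evidence table: genomic position, genetic-map positions, stratum label,
# Y-SNP counts by evidence class (segr = cross segregation; lat / dio = wild
# male-specific SNPs per species), X:Y synonymous divergence and reconstructed
# Y-CDS length. Transcribed by hand from the source table; cells whose printed
# digits are ambiguous are listed in the `uncertain` column (comma-separated
# field names) and should not be relied on individually.
gene_id	pos_kb	map_f_cM	map_m_cM	stratum	n_segr	n_lat	n_dio	ks	ycds_bp	ycds_pct	uncertain
1007	22029	37.26	47.15	PAR
1018	22455	37.26	47.15	PAR
1020	22530	37.26	47.15	PAR
1060	23958	39.22	49.11	PAR
1071	24299	39.22	49.11	PAR
1075	24708	39.22	49.11	PAR
1080	24843	39.22	49.11	PAR	2			0.016	566	51
1098	25582	39.22	49.11	PAR
1103	25942	39.22	49.11	PAR	1			0.014	115	4	ycds_bp,ycds_pct
1116	26638	39.22	49.11	PAR	3			0.014	687	37
1125	26872	39.22	49.11	PAR	1			0.012	393	65
# --- PAR / stratum 3 border ---
1129	27082	39.22	49.11	Str3	2	1		0.027	459	93
1130	27082			Str3	2	1		0.022	139	3	ycds_bp,ycds_pct
1133	27326	39.22	49.11	Str3	7	4		0.048	1284	51
1134	27333			Str3	2	2		0	162	58	ks,ycds_bp,ycds_pct
1135	27334	39.22	49.11	Str3	6	5		0.04	1086	92
1142	27746	39.22	49.11	Str3	10	3			604	5	n_segr,n_lat,ycds_bp,ycds_pct
1143	27774	39.22	49.11	Str3	11	5		0.016	1755	99	n_segr,n_lat
1144	27819	39.22	49.11	Str3	11	5		0.032	1332	99	n_segr,n_lat
1146	27853			Str3	5	2		0.037	861	75
1147	27902			Str3	23	16		0.062	1272	98
1148	27936	39.22	49.11	Str3	2	2		0.044	642	98
1151	27956	39.22	49.11	Str3	4	3		0.025	1410	89
1153	28108			Str3	10	4		0.056	815	98
1155	28131			Str3	3	3		0.009	1044	69
1171	28847			Str3	14	5		0.024	1383	67	n_segr,n_lat
1181	29139			Str3	10	5		0.022	1620	74
1182	29160			Str3	30	15		0.063	1929	99
1183	29269	39.22	49.11	Str3	35	18		0.079	2709	95
1184	29275	39.22	49.11	Str3	15	12		0.096	1662	97
1186	29286	39.22	49.11	Str3	8	6		0.066	530	99
1188	29293			Str3	8	3		0.067	501	99
1189	29294			Str3	3	2		0.022	108	8	ycds_bp,ycds_pct
1190	29342	39.22	49.11	Str3	6			0.074	489	84	n_lat
1191	29344	39.22	49.11	Str3	4	4		0.031	420	43
1192	29403			Str3	2			0.031	192	72	n_lat,ks,ycds_bp,ycds_pct
1196	29597			Str3	7	5		0.038	789	65
1200	29769	39.22	49.11	Str3	7	7		0.037	993	98
1201	29822	39.22	49.11	Str3	8	4		0.021	323	64	ks,ycds_bp
1204	29976	39.22	49.11	Str3	11	10		0.017	1350	95
1208	30261	39.22	49.11	Str3	2	2		0.044	312	99
1210	30273	39.22	49.11	Str3	7	5		0.059	1424	99
1215	30457			Str3	9	7		0.052	1050	91
1222	30591			Str3	4	2		0.11	659	93	ks,ycds_bp
1227	30628			Str3	3	3		0.063	435	33
1228	30654	39.22	49.11	Str3	22	11		0.049	1560	98
1241	31320	39.22	49.11	Str3	21	21		0.051	1601	99
1242	31349	39.22	49.11	Str3	10	5		0.086	1238	99
1243	31352	39.22	49.11	Str3	5	1		0.037	149	1	ycds_bp,ycds_pct
1244	31358			Str3	1			0.052	372	51	n_lat
1245	31381	39.22	49.11	Str3	2	1		0.054	74	34	ks,ycds_bp,ycds_pct
1249	31612			Str3	10	6		0.144	705	53
1258	31855			Str3	7	5		0.073	588	90
1259	31858			Str3	2	2		0.061	290	99
1266	32920	39.22	49.11	Str3	1	1		0.074	195	54
1277	34083	39.22	49.11	Str3	4	4		0.171	324	42	ks,ycds_bp
1285	34674			Str3	5	4		0.054	635	87
# --- Stratum 3 / stratum 2 border ---
1331	41574			Str2	32	32	19	0.044	2063	99
1335	41897			Str2	13	13	5	0.026	980	92
1341	42361		49.11	Str2	17	12	1	0.032	238	84	n_segr,n_lat,n_dio
1342	42372	39.22	49.11	Str2	3	3		0.046	521	99	n_dio
1352	43093	39.22	49.11	Str2	2	1		0.088	929	81	n_lat,n_dio
1359	43807	39.22	49.11	Str2	11	6	5	0.052	390	99	n_segr,n_lat,n_dio
1364	44614	39.22	49.11	Str2	3	2	2	0.067	572	67	n_segr,n_lat,n_dio
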