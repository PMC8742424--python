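sample_id	total_reads	level_pct	true_count	r1	r2	r3	r4	r5
SD01	30000	0.01	3	30	31	29	31	29
SD02	30000	0.1	30	57	58	56	57	55
SD03	30000	1	300	323	322	316	322	321
SD04	30000	2	600	621	620	610	617	614
SD05	30000	3	900	916	918	909	912	909
SD06	30000	4	1200	1211	1213	1207	1207	1206
SD07	30000	5	1500	1505	1507	1503	1502	1502
SD08	30000	6	1800	1801	1804	1802	1801	1798
SD09	30000	7	2100	2099	2100	2098	2094	2093
SD10	30000	8	2400	2397	2396	2393	2391	2390
SD11	30000	9	2700	2694	2691	2687	2686	2686
SD12	30000	10	3000	2991	2986	2985	2975	2982
SD13	30000	20	6000	5950	5945	5934	5934	5943
SD14	30000	30	9000	8912	8898	8895	8898	8900
SD15	30000	40	12000	11850	11859	11860	11859	11870
SD16	30000	50	15000	14812	14818	14817	14824	14825
SD17	30000	60	18000	17781	17790	17795	17779	17777
SD18	30000	70	21000	20752	20753	20757	20741	20738
SD19	30000	80	24000	23713	23726	23721	23716	23709
SD20	30000	90	27000	26671	26684	26684	26686	26678
SD21	30000	100	30000	29633	29651	29629	29652	29646
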