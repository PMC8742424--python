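species_id	replicate	total_mapped	unique_mapped
Anas_platyrhynchos	R1	17350	13548
Anas_platyrhynchos	R2	16381	13560
Anas_platyrhynchos	R3	35170	31664
Bos_taurus	R1	19884	3904
Bos_taurus	R2	10746	1840
Bos_taurus	R3	16668	3988
Camelus_bactrianus	R1	15221	5330
Camelus_bactrianus	R2	23387	16319
Camelus_bactrianus	R3	25856	17560
Canis_lupus_familiaris	R1	78416	37962
Canis_lupus_familiaris	R2	51085	25057
Canis_lupus_familiaris	R3	48068	21793
Equus_caballus	R1	49594	14541
Equus_caballus	R2	22297	8899
Equus_caballus	R3	42016	11305
Gallus_gallus	R1	22008	18504
Gallus_gallus	R2	14801	12181
Gallus_gallus	R3	9380	6094
Mus_musculus	R1	11717	4963
Mus_musculus	R2	8919	3896
Mus_musculus	R3	16902	10664
Mustela_putorius	R1	19235	3157
Mustela_putorius	R2	20029	8916
Mustela_putorius	R3	19847	7767
Myocastor_coypus	R1	40437	33785
Myocastor_coypus	R2	29178	24375
Myocastor_coypus	R3	15724	10892
Nyctereutes_procyonoides	R1	56355	16435
Nyctereutes_procyonoides	R2	27077	2348
Nyctereutes_procyonoides	R3	37645	11567
Oryctolagus_cuniculus	R1	10921	4016
Oryctolagus_cuniculus	R2	6602	1647
Oryctolagus_cuniculus	R3	10260	4778
Ovis_aries	R1	21377	7895
Ovis_aries	R2	12139	4084
Ovis_aries	R3	17950	6879
Rattus_norvegicus	R1	8875	1456
Rattus_norvegicus	R2	8239	2710
Rattus_norvegicus	R3	9832	3098
Sus_scrofa_domesticus	R1	42116	28114
Sus_scrofa_domesticus	R2	20722	12040
Sus_scrofa_domesticus	R3	33601	22651
Vulpes_vulpes	R1	92357	49294
Vulpes_vulpes	R2	62656	35156
Vulpes_vulpes	R3	53858	25960
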