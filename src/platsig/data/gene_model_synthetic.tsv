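gene	coding_length
TP53	1182
CDKN2A	471
FBXW7	2124
KRAS	570
REV3L	9390
EPYC	966
NOTCH1	7668
PIK3CA	3207
HRAS	570
CASP8	1440
GENE001	1592
GENE002	1952
GENE003	455
GENE004	3691
GENE005	573
GENE006	1575
GENE007	3867
GENE008	513
GENE009	1149
GENE010	1336
GENE011	1857
GENE012	2930
GENE013	1457
GENE014	2440
GENE015	2516
GENE016	2604
GENE017	3926
GENE018	2012
GENE019	2452
GENE020	1894
GENE021	1490
GENE022	1966
GENE023	3292
GENE024	2889
GENE025	3469
GENE026	2393
GENE027	3598
GENE028	2685
GENE029	732
GENE030	3521
GENE031	2908
GENE032	3464
GENE033	3982
GENE034	2478
GENE035	638
GENE036	1738
GENE037	3790
GENE038	1292
GENE039	2296
GENE040	1894
GENE041	2207
GENE042	2492
GENE043	3700
GENE044	3099
GENE045	3838
GENE046	1156
GENE047	2190
GENE048	2671
GENE049	1280
GENE050	3699
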