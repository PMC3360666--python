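case	inter_size	union_size	consistency	inter_tp	inter_pe	inter_se	inter_sp	inter_pr	union_tp	union_pe	union_se	union_sp	union_pr
3IU3_I	18	46	0.391	9	18	0.321	0.954	0.500	19	46	0.679	0.862	0.413
1HX1_B	18	52	0.346	4	18	0.167	0.841	0.222	15	52	0.625	0.580	0.288
1YY9_A	20	64	0.313	0	20	0.000	0.967	0.000	0	64	0.000	0.893	0.000
2ADF_A	0	42	0	0	0	0	1	0	13	55	0.867	0.759	0.236
1IQD_C	23	53	0.434	7	23	0.438	0.886	0.304	10	53	0.625	0.693	0.189
2GHW_A	20	54	0.37	8	20	0.276	0.931	0.400	14	69	0.483	0.684	0.203
2NY7_G	6	75	0.08	0	6	0.000	0.979	0.000	2	75	0.077	0.749	0.027
1WLP_B	29	63	0.46	8	29	0.276	0.807	0.276	18	63	0.621	0.587	0.286
1G9M_G	13	72	0.181	7	13	0.467	0.985	0.538	13	72	0.867	0.851	0.181
1E6J_P	28	43	0.651	11	28	1.000	0.915	0.393	11	43	1.000	0.839	0.256
2GRX_A	17	39	0.436	0	17	0.000	0.975	0.000	0	39	0.000	0.943	0.000
2GSK_A	4	68	0.059	0	4	0.000	0.993	0.000	8	68	0.190	0.891	0.118
1FLT_X	8	50	0.16	0	8	0.000	0.892	0.000	11	50	0.524	0.473	0.220
1SHY_A	29	59	0.492	5	29	0.217	0.886	0.172	8	59	0.348	0.758	0.136
1SQ0_A	27	42	0.643	7	27	0.259	0.893	0.259	8	42	0.296	0.818	0.190
1D4V_B	15	54	0.278	0	15	0.000	0.896	0.000	5	54	0.263	0.660	0.093
3BT1_A	0	67	0	0	0	0	1	0	0	67	0.000	0.451	0.000
1EER_A	1	36	0.028	0	1	0.000	0.992	0.000	7	36	0.184	0.773	0.194
1MQ8_B	0	46	0	0	0	0	1	0	7	46	0.412	0.756	0.152
3EZE_B	25	48	0.521	20	25	0.800	0.917	0.800	25	48	1.000	0.617	0.521
1II4_A	34	49	0.694	19	34	0.514	0.873	0.559	25	49	0.676	0.797	0.510
1HX1_A	0	83	0	0	0	0	1	0	6	83	0.286	0.797	0.072
1JRH_I	10	31	0.323	9	10	0.429	0.986	0.900	12	31	0.571	0.743	0.387
1BJ1_H	27	45	0.6	12	27	0.706	0.928	0.444	15	45	0.882	0.855	0.333
1N8Z_C	31	41	0.756	16	31	0.800	0.974	0.516	19	41	0.950	0.963	0.463
1ZTX_E	31	43	0.721	11	31	0.688	0.765	0.355	13	43	0.813	0.647	0.302
1AVZ_B	22	48	0.458	6	22	0.375	0.863	0.273	10	48	0.625	0.675	0.208
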