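case	mimopro_tp	mimopro_pe	mimopro_se	mimopro_sp	mimopro_pr	pep3d_tp	pep3d_pe	pep3d_se	pep3d_sp	pep3d_pr
3IU3_I	16	34	0.571	0.908	0.471	12	30	0.429	0.908	0.400
1HX1_B	14	38	0.583	0.727	0.368	5	32	0.208	0.693	0.156
1YY9_A	0	43	0.000	0.928	0.000	0	41	0.000	0.931	0.000
2ADF_A	13	24	0.867	0.937	0.542	0	31	0.000	0.822	0.000
1IQD_C	9	39	0.563	0.786	0.231	8	37	0.500	0.793	0.216
2GHW_A	14	38	0.483	0.862	0.368	8	36	0.276	0.839	0.222
2NY7_G	0	40	0.000	0.863	0.000	2	41	0.077	0.866	0.049
1WLP_B	9	47	0.310	0.651	0.191	17	45	0.586	0.743	0.378
1G9M_G	9	50	0.600	0.896	0.180	11	35	0.733	0.939	0.314
1E6J_P	11	42	1.000	0.844	0.262	11	29	1.000	0.910	0.379
2GRX_A	0	32	0.000	0.954	0.000	0	24	0.000	0.965	0.000
2GSK_A	8	40	0.190	0.942	0.200	0	32	0.000	0.942	0.000
1FLT_X	7	35	0.333	0.622	0.200	4	23	0.190	0.743	0.174
1SHY_A	6	44	0.261	0.820	0.136	7	44	0.304	0.825	0.159
1SQ0_A	8	34	0.296	0.861	0.235	7	35	0.259	0.850	0.200
1D4V_B	0	30	0.000	0.792	0.000	5	39	0.263	0.764	0.128
3BT1_A	0	40	0.000	0.672	0.000	0	27	0.000	0.779	0.000
1EER_A	7	26	0.184	0.852	0.269	0	11	0.000	0.914	0.000
1MQ8_B	7	30	0.412	0.856	0.233	0	16	0.000	0.900	0.000
3EZE_B	24	35	0.960	0.817	0.686	21	38	0.840	0.717	0.553
1II4_A	23	41	0.622	0.847	0.561	21	42	0.568	0.822	0.500
1HX1_A	0	46	0.000	0.879	0.000	6	37	0.286	0.918	0.162
1JRH_I	20	31	0.952	0.851	0.645	9	10	0.429	0.986	0.900
1BJ1_H	15	36	0.882	0.899	0.417	12	36	0.706	0.884	0.333
1N8Z_C	18	38	0.900	0.966	0.474	17	34	0.850	0.971	0.500
1ZTX_E	13	39	0.813	0.694	0.333	11	35	0.688	0.718	0.314
1AVZ_B	10	32	0.625	0.812	0.313	7	38	0.438	0.735	0.184
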