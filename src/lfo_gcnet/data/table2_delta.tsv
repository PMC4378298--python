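participant	intervention	delta_fma	dgc_LM1_to_SMA	dgc_SMA_to_LM1	dgc_SMA_to_LPMC
1	MP	6	-0.36	-0.23	-0.26
2	MP	7	0.00	0.08	0.07
3	MP	10	-0.06	0.02	0.10
4	MP	7	-0.01	-0.12	-0.15
5	MP	-2	-0.01	0.00	0.02
6	MP	0	0.01	-0.03	-0.06
7	MPPT	4	0.04	0.00	0.02
8	MPPT	9	0.1	0.10	0.02
9	MPPT	9	-0.02	0.04	0.19
10	MPPT	2	0.00	-0.17	0.02
11	MPPT	2	0.09	0.15	-0.03
12	MPPT	1	0.18	0.05	-0.00
13	MPPT	0	0.03	-0.06	-0.03
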