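species	class	chains	pct_hfd	pct_stam	printed_change
32:0PC	PC	16:0/16:0	1.06	1.09	+0.03
32:1PC	PC	16:0/16:1	1.02	0.24	-0.78
32:2PC	PC	14:0/18:2 16:1/16:1	0.17	0.13	-0.04
34:0PC	PC	16:0/18:0	0.14	0.24	+0.09
34:1PC	PC	16:0/18:1	16.64	8.71	-7.93
34:2PC	PC	16:0/18:2	23.37	19.91	-3.46
34:3PC-a	PC	16:1/18:2	1.40	1.01	-0.39
34:3PC-b	PC	16:0/18:3	1.11	0.57	-0.54
35:2PC	PC	17:0/18:2	0.18	0.35	+0.17
36:1PC	PC	18:0/18:1	1.05	1.37	+0.32
36:2PC	PC	18:0/18:2	3.97	7.56	+3.59
36:3PC	PC	16:0/20:3	2.21	3.09	+0.89
36:4PC-a	PC	16:0/20:4	19.80	15.38	-4.42
36:4PC-b	PC	18:2/18:2	0.50	1.27	+0.77
36:5PC	PC	16:1/20:4	0.57	0.20	-0.36
37:4PC	PC	17:0/20:4	0.14	0.29	+0.15
38:3PC-a	PC	18:0/20:3	0.36	1.01	+0.65
38:3PC-b	PC	n.d.	0.14	0.19	+0.05
38:4PC-a	PC	18:0/20:4	6.07	13.54	+7.47
38:4PC-b	PC	18:1/20:3	0.15	0.26	+0.11
38:5PC-a	PC	18:1/20:4	2.76	3.10	+0.34
38:5PC-b	PC	16:0/22:5	1.27	0.69	-0.57
38:6PC-a	PC	16:0/22:6	10.50	12.07	+1.58
38:6PC-b	PC	18:2/20:4	0.49	0.74	+0.25
38:7PC	PC	16:1/22:6	0.33	0.20	-0.13
39:6PC	PC	n.d.	0.06	0.14	+0.08
40:5PC-a	PC	18:0/22:5	0.48	0.46	-0.02
40:5PC-b	PC	20:1/20:4	0.17	0.18	+0.01
40:6PC-a	PC	18:0/22:6	2.11	3.92	+1.82
40:6PC-b	PC	n.d.	0.22	0.15	-0.07
40:7PC	PC	18:1/22:6	1.22	1.35	+0.13
40:8PC	PC	18:2/22:6 20:4/20:4	0.21	0.41	+0.20
38:5e/pPC	PC	16:0e/22:5 18:1e/20:4	0.13	0.15	+0.02
34:1PE	PE	16:0/18:1	0.74	0.34	-0.40
34:2PE	PE	16:0/18:2	4.15	2.25	-1.90
36:1PE	PE	18:0/18:1	0.24	0.26	+0.03
36:2PE	PE	18:0/18:2	2.44	3.81	+1.37
36:3PE	PE	18:1/18:2	2.16	2.00	-0.17
36:4PE-a	PE	16:0/20:4	8.22	5.52	-2.70
36:4PE-b	PE	18:2/18:2	0.15	0.31	+0.16
36:5PE	PE	16:1/20:4	0.48	0.13	-0.36
37:4PE	PE	17:0/20:4	0.31	0.44	+0.13
38:3PE	PE	18:0/20:3	0.30	0.70	+0.40
38:4PE	PE	18:0/20:4	30.82	35.41	+4.59
38:5PE-a	PE	18:1/20:4	5.72	5.71	-0.02
38:5PE-b	PE	16:0/22:5	2.41	1.35	-1.06
38:6PE-a	PE	16:0/22:6	25.48	21.28	-4.19
38:6PE-b	PE	18:2/20:4	0.22	0.38	+0.17
38:7PE	PE	16:1/22:6	0.55	0.16	-0.39
39:4PE-a	PE	19:0/20:4	0.20	0.25	+0.05
39:4PE-b	PE	19:0/20:4	0.19	0.10	-0.09
39:6PE	PE	17:0/22:6	0.17	0.30	+0.13
40:4PE	PE	18:0/22:4	0.32	0.43	+0.11
40:5PE-a	PE	18:0/22:5	1.16	1.00	-0.16
40:5PE-b	PE	18:0/22:5 20:1/20:4	0.34	0.32	-0.02
40:6PE-a	PE	18:0/22:6	5.93	9.15	+3.22
40:6PE-b	PE	18:1/22:5	0.91	0.73	-0.18
40:7PE	PE	18:1/22:6	4.67	5.21	+0.54
40:8PE	PE	18:2/22:6	0.17	0.38	+0.21
36:5e/pPE	PE	16:0p/20:4	0.74	0.84	+0.10
38:5e/pPE	PE	18:0p/20:4	0.54	0.84	+0.29
38:6e/pPE	PE	18:1p/20:4	0.27	0.37	+0.10
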