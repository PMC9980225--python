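event	seqname	start	stop	length	depth_gr
CNV1	Chr1	54792251	54809000	16749	2.39
CNV2	Chr3	1666751	1701750	34999	22.03
CNV3	Chr3	2719751	2767250	47499	22.46
CNV4	Chr4	30001501	30024250	22749	3.31
CNV5	Chr4	32703001	32731250	28249	9.19
CNV6	Chr5	10538001	10552000	13999	2.23
CNV7	Chr5	13291251	13298500	7249	2.22
CNV8	Chr6	120001	124750	4749	2.18
CNV9	Chr6	142751	153250	10499	3.40
CNV10	Chr7	27384251	27401750	17499	2.03
CNV11	Chr7	35146001	35150750	4749	2.14
CNV12	Chr7	40076251	40112750	36499	3.68
CNV13	Chr8	42437251	42510250	72999	2.06
CNV14	Chr9	11015251	11024750	9499	5.86
CNV15	Chr9	18044251	18072250	27999	2.80
CNV16	Scaffold12	46751	94500	47749	3.29
CNV17	Scaffold12	121751	135250	13499	4.66
CNV18	Scaffold26	99251	118500	19249	4.71
CNV19	Scaffold29	32251	58000	25749	3.04
CNV20	Scaffold29	88251	124750	36499	4.28
CNV21	Scaffold30	13251	123250	109999	32.46
CNV22	Scaffold35	10001	120500	110499	2.93
CNV23	Scaffold36	1	38500	38499	3.04
CNV24	Scaffold36	52001	88750	36749	2.16
CNV25	Scaffold36	104751	117250	12499	5.38
CNV26	Scaffold44	1	93250	93249	47.34
CNV27	Scaffold45	1	50250	50249	2.07
CNV28	Scaffold45	68001	91000	22999	5.88
CNV29	Scaffold47	1251	80000	78749	45.20
CNV30	Scaffold49	1	77750	77749	65.48
CNV31	Scaffold51	1	23250	23249	2.25
CNV32	Scaffold55	1	16250	16249	3.84
CNV33	Scaffold56	37251	65500	28249	6.15
CNV34	Scaffold58	48501	64000	15499	4.42
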