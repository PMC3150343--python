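probe_id	sampleA	sampleB	sampleC
G3P00	20	1	5
G3P01	21	2	6
G3P02	22	3	7
G3P03	23	4	8
G3P04	24	5	9
G3P05	25	6	10
G3P06	26	7	11
G3P07	27	8	12
G1P00	1	30	13
G1P01	2	31	14
G1P02	3	32	1
G1P03	4	33	2
BG00	10	10	3
BG01	11	11	4
BG02	12	12	15
BG03	13	13	16
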