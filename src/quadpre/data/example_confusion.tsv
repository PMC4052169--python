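# Published 6-class benchmark prediction matrix used as the worked example.
# rows = true class, columns = predicted class; class order 1 2 3 4 6 8
285	55	12	1	5	8
185	104	9	8	7	25
24	9	13	0	1	6
55	50	3	28	4	15
18	20	6	0	16	7
22	8	5	0	2	24
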