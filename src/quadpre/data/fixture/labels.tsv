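c1_0000	1
c1_0001	1
c1_0002	1
c1_0003	1
c1_0004	1
c1_0005	1
c1_0006	1
c1_0007	1
c1_0008	1
c1_0009	1
c1_0010	1
c1_0011	1
c2_0000	2
c2_0001	2
c2_0002	2
c2_0003	2
c2_0004	2
c2_0005	2
c2_0006	2
c2_0007	2
c2_0008	2
c2_0009	2
c2_0010	2
c2_0011	2
c3_0000	3
c3_0001	3
c3_0002	3
c3_0003	3
c3_0004	3
c3_0005	3
c3_0006	3
c3_0007	3
c3_0008	3
c3_0009	3
c3_0010	3
c3_0011	3
c4_0000	4
c4_0001	4
c4_0002	4
c4_0003	4
c4_0004	4
c4_0005	4
c4_0006	4
c4_0007	4
c4_0008	4
c4_0009	4
c4_0010	4
c4_0011	4
c6_0000	6
c6_0001	6
c6_0002	6
c6_0003	6
c6_0004	6
c6_0005	6
c6_0006	6
c6_0007	6
c6_0008	6
c6_0009	6
c6_0010	6
c6_0011	6
c8_0000	8
c8_0001	8
c8_0002	8
c8_0003	8
c8_0004	8
c8_0005	8
c8_0006	8
c8_0007	8
c8_0008	8
c8_0009	8
c8_0010	8
c8_0011	8
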