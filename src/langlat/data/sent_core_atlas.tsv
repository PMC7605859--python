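pair_name	hemisphere	volume_mm3	is_hub
AG2	L	8613.7	0
AG2	R	5972.6	0
F1_2	L	4004.3	0
F1_2	R	6196.8	0
F2p	L	6771.6	0
F2p	R	1557.8	0
F3O1	L	5679.9	0
F3O1	R	5188.0	0
F3t	L	5497.0	1
F3t	R	5612.0	1
INSa2	L	1485.3	0
INSa2	R	8948.3	0
INSa3	L	7909.4	0
INSa3	R	5487.2	0
PrG4	L	3240.3	0
PrG4	R	7722.3	0
SMA3	L	5130.5	0
SMA3	R	3194.1	0
SMG7	L	3011.1	0
SMG7	R	6076.4	0
STS1	L	4218.7	0
STS1	R	6822.0	0
STS2	L	7356.8	0
STS2	R	7177.0	0
STS3	L	7447.0	1
STS3	R	8186.3	1
STS4	L	6172.5	1
STS4	R	3815.9	1
T1_4	L	1476.8	0
T1_4	R	2745.7	0
T2_3	L	1931.9	0
T2_3	R	1704.3	0
T2_4	L	2169.6	0
T2_4	R	4157.6	0
T3_4	L	5469.0	0
T3_4	R	3977.5	0
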