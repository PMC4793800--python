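perturbation	set	up	nc	down
blumeria_graminis	R	6	5	5
blumeria_graminis	control	5	15	6
blumeria_graminis	stress	11	7	17
hyaloperonospora_parasitica_noco2	R	33	25	2
hyaloperonospora_parasitica_noco2	control	12	28	14
hyaloperonospora_parasitica_noco2	stress	52	26	17
powdery_mildew	R	35	11	2
powdery_mildew	control	5	18	1
powdery_mildew	stress	22	31	8
pst_avrrpm1	R	8	3	3
pst_avrrpm1	control	6	4	0
pst_avrrpm1	stress	10	15	7
psm_avrrpt2	R	36	16	9
psm_avrrpt2	control	24	16	17
psm_avrrpt2	stress	45	10	34
pst_hopz1a	R	26	15	11
pst_hopz1a	control	16	8	9
pst_hopz1a	stress	40	20	27
pst_dc3000	R	2	10	14
pst_dc3000	control	4	6	2
pst_dc3000	stress	6	37	10
flg22	R	4	4	0
flg22	control	8	5	5
flg22	stress	5	6	13
salicylic_acid_lt24h	R	47	18	4
salicylic_acid_lt24h	control	14	17	8
salicylic_acid_lt24h	stress	33	76	31
salicylic_acid_gt24h	R	0	18	21
salicylic_acid_gt24h	control	0	6	3
salicylic_acid_gt24h	stress	3	32	11
excess_light	R	5	33	34
excess_light	control	11	29	13
excess_light	stress	35	57	48
heat_37c	R	7	23	22
heat_37c	control	11	15	13
heat_37c	stress	18	39	32
cold_4c	R	13	45	24
cold_4c	control	15	35	16
cold_4c	stress	56	65	36
drought	R	18	30	4
drought	control	8	23	7
drought	stress	30	36	25
ozone	R	8	6	3
ozone	control	2	6	3
ozone	stress	17	9	9
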