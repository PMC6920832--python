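suborder	families	genera	species	sequences
Suborder_1	1	5	5	5
Suborder_2	1	3	6	10
Suborder_3	1	3	8	15
Suborder_4	1	28	44	144
Suborder_5	1	1	1	1
Suborder_6	1	1	1	1
Suborder_7	1	1	1	1
Suborder_8	1	1	1	2
Suborder_9	1	2	2	2
Suborder_10	1	1	1	1
Suborder_11	2	3	3	4
Suborder_12	1	1	1	1
Suborder_13	1	2	2	2
Suborder_14	2	3	3	7
Nannocystaceae	11	157	309	1044
Suborder_15	10	48	108	236
Cystobacterineae	6	50	131	1328
Suborder_16	4	54	116	533
Suborder_17	6	32	60	207
Sorangiineae	5	49	195	1453
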