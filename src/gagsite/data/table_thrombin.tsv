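label	dG_ES	ddG_ES	dG_DS	ddG_DS	Kd_nM	ddG_OBS	comparator
Wt	-503.1	0	461.9	0	90	0	Wt
K169E	-275.9	73.8	392.4	-69.4	150	0.31	Wt
R175E	-401.6	101.5	366.8	-95.1	570	1.11	Wt
R233E	-337.3	165.8	311.5	-150.4	720	1.25	Wt
K236E	-275.9	227.2	255.5	-206.4	4800	2.38	Wt
K240E	-282.6	220.5	262.5	-199.4	1000	1.44	Wt
R233E-K240E	-117.1	220.2	111.8	-199.7	16000	3.11	R233E
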