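label	dG_ES	ddG_ES	dG_DS	ddG_DS	Kd_nM	ddG_OBS	comparator
Wt	-199.8	0	184.6	0	6	0	Wt
K125Q	-125.1	74.7	116.6	-68.0	12	0.4	Wt
K136T	-200.0	-0.25	185.0	0.4	6	0	Wt
N135A	-198.9	0.8	183.7	-0.9	2	-0.6	Wt
N135A/R129Q	-150.7	48.2	139.2	-45.4	1800	3.4	N135A
N135A/R129H	-151.7	47.2	139.8	-43.9	820	2.9	N135A
N135A/K114A	-85.4	113.5	80.2	-103.5	1800000	7.6	N135A
R132M	-156.7	43.0	145.2	-39.4	89	1.6	Wt
K133M	-159.4	40.4	147.0	-37.6	171	2.0	Wt
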