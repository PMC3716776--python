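# Bundled default single-copy marker set: 54 COG families, 30 flagged ribosomal.
# Stand-in list of universal single-copy families; completeness weighting only
# depends on the 54/30 structure, not on the specific ids.
cog_id	is_ribosomal
COG0048	1
COG0049	1
COG0051	1
COG0052	1
COG0080	1
COG0081	1
COG0087	1
COG0088	1
COG0089	1
COG0090	1
COG0091	1
COG0092	1
COG0093	1
COG0094	1
COG0096	1
COG0097	1
COG0098	1
COG0099	1
COG0100	1
COG0102	1
COG0103	1
COG0184	1
COG0185	1
COG0186	1
COG0197	1
COG0198	1
COG0199	1
COG0200	1
COG0222	1
COG0244	1
COG0012	0
COG0013	0
COG0016	0
COG0017	0
COG0018	0
COG0030	0
COG0060	0
COG0085	0
COG0086	0
COG0124	0
COG0143	0
COG0172	0
COG0201	0
COG0202	0
COG0215	0
COG0343	0
COG0442	0
COG0495	0
COG0504	0
COG0519	0
COG0525	0
COG0533	0
COG0541	0
COG0552	0
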