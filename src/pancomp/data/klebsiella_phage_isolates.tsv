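phage_name	genome_size_bp	n_genes	n_introns	n_trnas	family	genus	accession
vB_KM5a1-KLB1	171972	263	3	1	Straboviridae	Slopekvirus	PP444686
vB_KM5a1-KLB3	176987	282	0	2	Straboviridae	Slopekvirus	PP444687
vB_KM5a1-KLB10	174281	282	3	2	Straboviridae	Slopekvirus	PP505786
vB_KM5a1-KLB13	174344	277	4	2	Straboviridae	Slopekvirus	PP505787
vB_KM5a1-KLB15	174800	277	1	2	Straboviridae	Slopekvirus	PP526028
vB_KM5a1-KLB21	177853	278	5	2	Straboviridae	Slopekvirus	PP597383
vB_KM5a1-KLB23	175398	278	3	2	Straboviridae	Slopekvirus	PP554337
vB_KM5a1-KLB25	174636	278	3	2	Straboviridae	Slopekvirus	PP556864
vB_KM5a1-KLB27	176864	276	4	2	Straboviridae	Slopekvirus	PP582754
vB_KM5a1-KLB2	165103	286	3	17	Straboviridae	Jiaodavirus	PP597384
vB_KM5a1-KLB8	165787	290	3	17	Straboviridae	Jiaodavirus	PP444688
vB_KM5a1-KLB31	176609	310	5	6	Straboviridae	Kanagawavirus	PP582757
vB_KM5a1-KLB19	52663	88	1	1	Drexlerviridae	Vilniusvirus	PP526029
vB_KM5a1-KLB26	51740	85	1	0	Drexlerviridae	unclassified	PP556865
vB_KM5a1-KLB4	38788	49	0	0	Autographiviridae	Teetrevirus	PP197344
vB_KM5a1-KLB7	38140	48	0	0	Autographiviridae	Teetrevirus	PP582758
vB_KM5a1-KLB12	38195	47	0	0	Autographiviridae	Teetrevirus	PP597382
vB_KM5a1-KLB16	44851	70	0	0	Ca. Mavericviridae	Alumvirus	PP197198
vB_KM5a1-KLB22	45183	72	0	0	Ca. Mavericviridae	Buckeyevirus	PP554336
vB_KM5a1-JVSB2	47362	65	0	0	Ca. Mavericviridae	Ashvirinae	PP444685
vB_KM5a1-KLB5	39747	60	0	0	Ca. Rivulusviridae	Darbyvirus	PP202993
vB_KM5a1-KLB24	40194	53	0	0	Ca. Rivulusviridae	Sherbvirus	PP554338
vB_KM5a1-KLB28	40269	55	0	0	Ca. Rivulusviridae	Sherbvirus	PP582755
vB_KM5a1-KLB29	40017	53	0	0	Ca. Rivulusviridae	Colbvirus	PP582756
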