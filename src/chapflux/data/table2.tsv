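gene	orf	chaperone_class	chaperone_cpc	n_substrates	substrate_volume_cpc	substrate_flux_cpc_per_min
Ssb2	YNL209W	HSP70	85650	172	13675400	1172700
Ssb1	YDL229W	HSP70	68570	348	9666400	743300
Ssz1	YHR064C	HSP70	63090	115	6167800	423800
Ssc1	YJR045C	HSP70	58050	40	2802400	346700
Ssa4	YER103W	HSP70	5700	29	2261500	323800
Zuo1	YGR285C	HSP40	31290	89	4628100	314100
Hsc82	YMR186W	HSP90	84370	90	3853900	274600
Ssa1	YAL005C	HSP70	335460	179	3210800	247100
Cct2	YIL142W	CCT	7070	29	1080700	159000
Cct4	YDL143W	CCT	20010	32	1044700	150000
Hsp60	YLR259C	HSP60	46960	30	1083200	122800
Sse1	YPL106C	HSP70	61980	79	2408400	120300
Hsp82	YPL240C	HSP90	23040	89	1338500	103000
Kar2	YJL034W	HSP70	26300	66	935100	96300
Gim3	YNL153C	PFD	4060	120	1162300	95400
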