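chaperone_class	gene	orf	uniprot	cpc	sem	qtype	bound_cpc
SMALL	Hsp12	YFL014W	P22943	439000	35500	A
SMALL	Hsp26	YBR072W	P15992	235000	33500	A
SMALL	Hsp42	YDR171W	Q12329	9150	450	A
SMALL	Hsp31	YDR533C	Q04432	6450	550	A
PFD	Gim4	YEL003W	P40005	9650	300	A
PFD	Pac10	YGR078C	P48363	4750	200	A
PFD	Gim3	YNL153C	P53900	4050	350	A
PFD	Yke2	YLR200W	P52553	3050	300	A
PFD	Pfd1	YJL179W	P46988	2950	200	A
PFD	Gim5	YML094W	Q04493	2000	100	A
HSP90	Hsc82	YMR186W	P15108	84500	2000	A
HSP90	Hsp82	YPL240C	P02829	23000	1000	A
HSP70	Ssa1	YAL005C	P10591	335500	25500	A
HSP70	Ssb2	YNL209W	P40150	85500	3500	A
HSP70	Ssb1	YDL229W	P11484	68500	1500	A
HSP70	Ssz1	YHR064C	P38788	63000	3500	A
HSP70	Sse1	YPL106C	P32589	62000	2000	A
HSP70	Ssc1	YJR045C	P12398	58000	4000	A
HSP70	Ssa2	YLL024C	P10592	58000	2500	A
HSP70	Kar2	YJL034W	P16474	26500	1500	A
HSP70	Sse2	YBR169C	P32590	5700	250	A
HSP70	Ssa4	YER103W	P22202	5700	50	A
HSP70	Ssq1	YLR369W	Q05931	2300	100	A
HSP70	Lhs1	YKL073W	P36016	2450	300	A
HSP70	Ssa3	YBL075C	P09435	660	55	A
HSP60	Hsp60	YLR259C	P19882	47000	2500	A
HSP40	Zuo1	YGR285C	P32527	31500	1500	A
HSP40	Sis1	YNL007C	P25294	15000	500	A
HSP40	Sec63	YOR254C	P14906	11000	500	A
HSP40	Caj1	YER048C	P39101	5000	300	A
HSP40	Tim14	YLR008C	Q07914	4000	100	A
HSP40	Erj5	YFR041C	P43613	3400	100	A
HSP40	Mdj1	YFL016C	P35191	3200	200	A
HSP40	Swa2	YDR320C	Q06677	1550	50	A
HSP40	Scj1	YMR214W	P25303	1500	100	A
HSP40	Djp1	YIR004W	P40564	1050	100	A
HSP40	Jjj1	YNL227C	P53863	500	80	A
HSP40	Jac1	YGL018C	P53193	470	210	A
HSP40	Jem1	YJL073W	P40358	450	40	A
HSP40	Xdj1	YLR090W	P39102	330	20	A
HSP40	Mdj2	YNL328C	P42834	250	50	A
CCT	Cct6	YDR188W	P39079	5300	900	A
CCT	Cct4	YDL143W	P39078	20000	1000	A
CCT	Tcp1	YDR212W	P12612	11500	1000	A
CCT	Cct2	YIL142W	P39076	7050	550	A
CCT	Cct5	YJR064W	P40413	6300	150	A
CCT	Cct8	YJL008C	P47079	6000	100	A
CCT	Cct7	YJL111W	P42943	2900	100	A
AAA+	Hsp104	YLL026W	P31539	27500	2000	A
AAA+	Hsp78	YDR258C	P33416	10500	500	A
AAA+	Mcx1	YBR227C	P38323	1200	250	A
HSP70	Ecm10	YEL030W	P39987			B/B	600
HSP40	Cwc23	YGL128C	P52868			B/B	600
HSP40	Jjj2	YJL162C	P46997			B/B	6000
HSP40	Jjj3	YJR097W	P47138			B/B	600
HSP40	Jid1	YPR061C	Q12350			B/B	600
HSP40	Hlj1	YMR161W	P48353			B/C	600
HSP40	Apj1	YNL077W	P53940			B/C	6000
CCT	Cct3	YJL014W	P39077			B/C	600
SMALL	Sno4	YMR322C	Q04902			B/C	600
SMALL	Hsp33	YOR391C	Q08914			B/C	600
SMALL	Hsp32	YPL280W	Q08992			B/C	600
HSP40	Ydj1	YNL064C	P25491			C/C
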