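variant	event_kind	consequence	pct_transcripts	homozygous	was_missense
c.855+1delG	splice	p.V286WfsX2	27	0	0
c.857T>A	missense	p.Val286Glu	50-60	0	1
c.857T>A	splice	p.Val286_Arg302del	3-5	0	1
c.907-3C>A	splice	p.Met303GlyfsX25	49	0	0
c.907-3C>A	splice	p.Val286GlyfsX25	10	0	0
c.1053+1G>A	splice	p.Arg313ProfsX8	5	0	0
c.1053+1G>A	splice	p.His314GlufsX9	10	0	0
c.1053+1G>A	splice	p.Val286_Pro351del	7	0	0
c.1171_1180+4dup14	splice	p.Met394SerfsX10	100	1	0
c.1180+5G>A	splice	p.Met394SerfsX27	20	0	0
c.1180+5G>A	splice	p.Val385TrpfsX5	12	0	0
c.1481-1G>A	splice	p.Glu494GlyfsX16	ND	0	0
c.1639-6T>A	splice	p.Gly547AlafsX24	43	0	0
c.2163-2A>G	splice	p.Gln722LeufsX26	34	0	0
c.2163-2A>G	splice	p.Gln722ProfsX51	10	0	0
c.2643+1G>A	splice	p.Tyr838_Thr881del	31-60	0	0
c.2643+5G>A	splice	p.Tyr838_Thr881del	32	0	0
c.2810+1G>A	splice	p.Tyr882SerfsX4	ND	0	0
c.2810+1G>A	splice	p.Trp930_Thr937del	ND	0	0
c.2811-2A>C	splice	p.Leu938ArgfsX3	12	0	0
c.2811-2A>C	splice	p.Leu938ArgfsX16	8	0	0
c.2811-2A>C	splice	p.Leu938AlafsX15	3	0	0
c.2811-20T>G	splice	p.Leu938ArgfsX3	ND	0	0
c.3031+2T>C	splice	p.Asn976AlafsX46	37	0	0
c.3031G>C	splice	p.Gly1011Argfs	40	0	1
c.3031G>C	splice	p.Asn976AlafsX46	8	0	1
c.4794G>T	missense	p.K1598N	15-18	0	1
c.4794G>T	splice	p.G1547_K1598del	26-30	0	1
c.4886+1249G>T	splice	p.Lys1646_Met1647ins59	26	0	0
c.4886+1249G>T	splice	p.Lys1646AsnfsX13	4	0	0
c.5057+5G>A	splice	p.Gly1660AlafsX36	27	0	0
c.5057+5G>A	splice	p.Cys1685SerfsX36	3	0	0
c.5057+5G>A	splice	p.Ser1687TyrfsX20	7	0	0
c.5057+5G>T	splice	p.Gly1660AlafsX36	45	0	0
c.5057+5G>T	splice	p.Cys1685SerfsX36	8	0	0
c.5429+1G>T	splice	p.Gly178ValfsX17	48	0	0
c.5429G>A	splice	p.Gly178ValfsX17	100	1	1
c.5503A>G	splice	p.Met1835LeufsX6	46	0	1
c.5526-7T>G	splice	p.Gly1842_Trp1843insSerSer	95	1	0
c.5668-7G>A	splice	p.Asp1890ValfsX78	29-33	0	0
c.5668-824C>T	splice	p.Asp1890GlyfsX47	17	0	0
c.5768-1G>C	splice	p.Gly1923AlafsX23	25	0	0
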