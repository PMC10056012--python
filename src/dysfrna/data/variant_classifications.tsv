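variant	prior_call	study_class	novel
c.17T>A	VUS (ClinVar)	VUS	0
c.89_236del exons 2-3 deletion	Pathogenic (ClinVar)	Pathogenic	0
c.125dupT	Novel variant	Pathogenic	1
c.237_342del exon 4 deletion	Novel variant	Pathogenic	1
c.331C>T	Pathogenic (literature)	Pathogenic	0
c.401C>T	VUS/Likely Pathogenic (ClinVar)	Likely Benign	0
c.509C>A	VUS/Likely Benign/Benign (ClinVar)	Likely Benign	0
c.533delG	Likely Pathogenic (LOVD)	Pathogenic	0
c.757C>T	Pathogenic (literature)	Pathogenic	0
c.855+1delG	Pathogenic (literature)	Pathogenic	0
c.857T>A	Pathogenic (literature)	Likely Pathogenic	0
c.863dupA	Pathogenic (LOVD)	Pathogenic	0
c.865T>C	VUS (ClinVar)	Likely Pathogenic	0
c.896G>A	VUS (ClinVar, literature)	Likely Pathogenic	0
c.907-2774_3873+827del duplication of exons 10-35	Novel variant	Likely Pathogenic	1
c.907-3C>A	VUS (ClinVar)	Likely Pathogenic	0
c.1004G>C	Benign (LOVD)	VUS	0
c.1053+1G>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.1071delC	Pathogenic (LOVD)	Pathogenic	0
c.1168G>A	Pathogenic (literature)	Likely Pathogenic	0
c.1171_1180+4dup14	Pathogenic/Likely Pathogenic (ClinVar)	Likely Pathogenic	0
c.1180+5G>A	Pathogenic (literature)	Pathogenic	0
c.1368C>A	Pathogenic (literature)	Pathogenic	0
c.1392dupA	Pathogenic (literature)	Pathogenic	0
c.1481-1G>A	Pathogenic (ClinVar)	Pathogenic	0
c.1517C>G	Pathogenic (LOVD)	Pathogenic	0
c.1639-6T>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.1663C>T	Pathogenic (literature)	Pathogenic	0
c.1668_1669insGTT	VUS (ClinVar)	Likely Pathogenic	0
c.1834C>T	Pathogenic (literature)	Pathogenic	0
c.1852G>A	VUS/Likely Pathogenic (ClinVar, literature)	Pathogenic	0
c.1861G>A	Pathogenic (literature)	Pathogenic	0
c.1877T>C	VUS (ClinVar, literature)	Likely Benign	0
c.1948delC	Pathogenic (literature)	Pathogenic	0
c.1966A>G	VUS/Likely Benign (ClinVar)	VUS	0
c.2071C>T	Pathogenic (LOVD)	Pathogenic	0
c.2077delC	Pathogenic (LOVD)	Pathogenic	0
c.2079C>T	VUS/Likely Benign (ClinVar)	VUS	0
c.2163-2A>G	Pathogenic (literature)	Pathogenic	0
c.2332C>T	VUS/Likely Benign (ClinVar)	VUS	0
c.2496_2499delGACA	Pathogenic (literature)	Pathogenic	0
c.2512_3174del exons 25-29 deletion	Pathogenic (LOVD)	Pathogenic	0
c.2643+1G>A	Pathogenic (literature)	Pathogenic	0
c.2643+5G>A	Novel variant	Likely Pathogenic	1
c.2790G>C	VUS (ClinVar)	Likely Pathogenic	0
c.2810+1G>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.2811-20T>G	Novel variant	Likely Pathogenic	1
c.2811-2A>C	Pathogenic (literature)	Pathogenic	0
c.2875C>T	Pathogenic (literature)	Pathogenic	0
c.2894G>A	Pathogenic (literature)	Pathogenic	0
c.2929G>A	VUS (ClinVar)	VUS	0
c.3022G>A	VUS (ClinVar)	VUS	0
c.3031G>C	Pathogenic (LOVD)	Likely Pathogenic	0
c.3031+2T>C	Pathogenic (literature)	Pathogenic	0
c.3051dupC	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.3065G>A	Benign/Likely Benign (ClinVar)	Likely Benign	0
c.3112C>T	Pathogenic (literature)	Pathogenic	0
c.3113G>A	Pathogenic (literature)	Pathogenic	0
c.3113G>C	Novel variant	Likely Pathogenic	1
c.3137G>A	Pathogenic (literature)	Pathogenic	0
c.3191_3196dupCGGAGG	Benign/Likely Benign (ClinVar)	Likely Benign	0
c.3444T>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.3445G>A	VUS (ClinVar)	VUS	0
c.3466T>C	VUS (ClinVar)	VUS	0
c.3517dupT	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.3534C>T	VUS, Likely Benign, Benign (ClinVar)	Likely Benign	0
c.3702T>C	VUS/Likely Benign (ClinVar)	VUS	0
c.3703_3843del exon 34 deletion	Novel variant	Likely Pathogenic	1
c.3805dupG	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.3832C>T	Pathogenic (literature)	Pathogenic	0
c.3904_4410del exons 37-40 deletion	Novel variant	Likely Pathogenic	1
c.3967C>G	VUS/Likely Benign (ClinVar)	VUS	0
c.3992G>T	Benign/Likely Benign (ClinVar)	Likely Benign	0
c.4003G>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.4024C>T	VUS/Pathogenic (ClinVar)	Likely Pathogenic	0
c.4060_4062delTCC	VUS/Pathogenic (LOVD)	Likely Pathogenic	0
c.4090C>T	Pathogenic (ClinVar)	Pathogenic	0
c.4360G>T	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.4408C>T	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.4439A>C	VUS (ClinVar)	Likely Pathogenic	0
c.4509+1586dupG	Novel variant	VUS	1
c.4526T>G	Novel variant	VUS	1
c.4577A>C	VUS/Likely Benign (ClinVar, literature)	Likely Benign	0
c.4742G>A	VUS/Likely Benign/Pathogenic (ClinVar)	VUS	0
c.4756C>T	Pathogenic (literature)	Pathogenic	0
c.4794G>T	VUS (ClinVar)	Likely Pathogenic	0
c.4886+1249G>T	Pathogenic (ClinVar)	Likely Pathogenic	0
c.5022delT	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.5057+5G>A	Pathogenic/Likely Pathogenic (ClinVar)	Likely Pathogenic	0
c.5057+5G>T	VUS (ClinVar)	Likely Pathogenic	0
c.5059T>C	VUS (ClinVar)	Likely Pathogenic	0
c.5159delG	Of the type predicted to cause disease (UMD-DYSF)	Pathogenic	0
c.5181delA	Pathogenic (LOVD)	Pathogenic	0
c.5296G>A	VUS/Pathogenic (LOVD)	Likely Pathogenic	0
c.5341G>A	Novel variant	Likely Pathogenic	1
c.5429G>A	Pathogenic/Likely Pathogenic (ClinVar)	Pathogenic	0
c.5429+1G>T	Pathogenic (ClinVar)	Likely Pathogenic	0
c.5503A>G	VUS (ClinVar)	Pathogenic	0
c.5509G>A	Pathogenic (literature)	Pathogenic	0
c.5526-7T>G	VUS (ClinVar)	VUS	0
c.5668-7G>A	Pathogenic (literature)	Pathogenic	0
c.5668-824C>T	Pathogenic (literature)	Pathogenic	0
c.5698_5699delAG	Pathogenic (ClinVar)	Pathogenic	0
c.5768-1G>C	Likely Pathogenic (ClinVar)	Pathogenic	0
c.5768_5926del exon 52 deletion	Pathogenic (ClinVar)	Pathogenic	0
c.5836_5839delCAGC	Pathogenic (ClinVar)	Pathogenic	0
c.5979dupA	Pathogenic (literature)	Pathogenic	0
c.6038C>G	VUS (ClinVar)	Likely Pathogenic	0
c.6124C>T	Pathogenic (literature)	Pathogenic	0
c.6196G>A	VUS (ClinVar)	Likely Pathogenic	0
c.6216delC	Pathogenic (ClinVar)	VUS	0
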