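Sample	Gene	Duplicated region	cDNA change	Protein change	PKDB	# Patients	Classification	Ref counts	Variants counts	SV coordinates
03-106-P6	PKD1	Yes	c.1-?_8161+?del	p.(Met1fs)	Absent	0	Definitely pathogenic	-	-	g.2154344-2186386del
12-331-P1	PKD1	Yes	c.566C>G	p.(Ser189*)	Present	1	Definitely pathogenic	188	62	-
12-382-P1	PKD1	Yes	c.736_737del	p.(Ser246fs)	Absent	0	Definitely pathogenic	19	14	-
04-016-P6	PKD1	Yes	c.1831C>T	p.(Arg611Trp)	Present	1	Likely pathogenic	25	13	-
12-235-P1	PKD1	Yes	c.2329C>T	p.(Gln777*)	Absent	0	Definitely pathogenic	59	37	-
12-366-P1	PKD1	Yes	c.2478delC	p.(Ile827fs)	Absent	0	Definitely pathogenic	114	83	-
12-010-P1	PKD1	Yes	c.4888C>T	p.(Gln1630*)	Present	1	Definitely pathogenic	136	114	-
02-010-P6	PKD1	Yes	c.6583_6589del7	p.(Cys2195fs)	Present	1	Definitely pathogenic	74	79	-
10-326-P3	PKD1	Yes	c.6778_6780delATT	p.(Ile2260del)	Present	1	Highly likely Pathogenic	190	148	-
11-220-P2	PKD1	Yes	c.6221delA	p.(Asn2074fs)	Absent	0	Definitely Pathogenic	123	113	-
11-247-P7	PKD1	Yes	c.6384C>A	p.(Asn2128Lys)	Absent	0	Highly likely pathogenic	181	131	-
12-161-P1	PKD1	Yes	c.6586C>T	p.(Gln2196*)	Present	1	Definitely pathogenic	86	50	-
11-517-P1	PKD1	Yes	c.6736C>T	p.(Gln2246*)	Present	1	Definitely pathogenic	185	124	-
11-525-P2	PKD1	Yes	c.6827T>C	p.(Leu2276Pro)	Absent	0	Highly likely pathogenic	280	245	-
10-388-P3	PKD1	Yes	c.8161+1G>C	p.(?)	Absent	0	Definitely pathogenic	21	25	-
11-468-P1	PKD1	Yes	c.8251C>T	p.(Gln2751*)	Absent	0	Definitely Pathogenic	92	92	-
12-363-P1	PKD1	Yes	c.8285delT	p.(Ile2762fs)	Absent	0	Definitely Pathogenic	120	89	-
10-463-P3	PKD1	Yes	c.8311G>A	p.(Glu2771Lys)	Present	18	Highly likely pathogenic	58	63	-
11-457-P2	PKD1	Yes	c.8858A>G	p.(Asn2953Ser)	Absent	0	Highly likely pathogenic	236	191	-
11-287-P2	PKD1	Yes	c.9240_9241delAT	p.(Ala3082fs)	Present	3	Definitely pathogenic	164	80	-
10-193-P3	PKD1	Yes	c.9412G>A	p.(Val3138Met)	Present	2	Likely Pathogenic	208	188	-
11-595-P2	PKD1	Yes	c.9455_9456insC	p.(Arg3152fs)	Absent	0	Definitely pathogenic	283	184	-
07-172-P5	PKD1	Yes	c.9889G>A	p.(Val3297Met)	Absent	0	Likely pathogenic	130	114	-
09-403-P3	PKD1	Yes	c.10170+25_+45del19	p.(Gln3390fs)	Present	2	Highly likely pathogenic	96	26	-
10-182-P3	PKD1	Yes	c.11017-10C>A	p.(Arg3672fs)	Present	7	Highly likely pathogenic	109	83	-
12-144-P1	PKD1	No	c.10847C>A	p.(Ser3616*)	Absent	0	Definitely Pathogenic	224	177	-
10-353-P3	PKD1	No	c.11359_11360del	p.(Pro3788fs)	Absent	0	Definitely pathogenic	292	203	-
11-256-P2	PKD1	No	c.11471G>T	p.(Gly3824Val)	Absent	0	Likely pathogenic	85	63	-
11-168-P8	PKD1	No	c.12004-2A>G	p.(?)	Absent	0	Definitely pathogenic	143	113	-
09-446-P3	PKD1	No	c.12031C>T	p.(Gln4011*)	Present	4	Definitely pathogenic	106	85	-
11-133-P8	PKD2	No	c.224delC	p.(Pro75fs)	Absent	0	Definitely pathogenic	41	25	-
11-008-P3	PKD2	No	c.637C>T	p.(Arg213*)	Absent	0	Definitely pathogenic	198	172	-
11-170-P2	PKD2	No	c.965G>A	p.(Arg322Gln)	Present	4	Highly likely pathogenic	396	330	-
12-149-P1	PKD2	No	c.2050_2053del4	p.(Tyr684fs)	Present	1	Definitely pathogenic	212	181	-
11-571-P2	PKD2	No	c.709-?_2907+?del	p.(Leu237_Val968del)	Absent	0	Definitely pathogenic	-	-	g.88952828-89050618del
09-393-P3	-	-	-	-	-	-	-	-	-	-
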