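Sample	Gene	Duplicated region	cDNA change	Protein change	PKDB	# Patients	Classification	Ref counts	Variants counts	SV coordinates
06-056	PKD1	Yes	c.348_352delTTTAA	p.(Asn116fs)	Present	1	Definitely pathogenic	28	20	-
06-122	PKD1	Yes	c.7204C>T	p.(Arg2402*)	Present	2	Definitely pathogenic	24	12	-
07-032	PKD1	Yes	c.8421_8422insC	p.(Ile2808fs)	Absent	0	Definitely pathogenic	22	18	-
11-444	PKD1	Yes	c.8041C>T	p.(Arg2681Cys)	Absent	0	Highly likely pathogenic	38	20	-
12-444	PKD2	No	c.1532_1533insAT	p.(Asp511fs)	Absent	0	Definitely pathogenic	156	70	-
12-444	PKD1	No	c.10921C>T	p.(Arg3642Cys)	Absent	0	Highly likely pathogenic	40	52	-
12-505	PKD1	Yes	c.50174_5015delAG	p.(Arg1672fs)	Present	28	Definitely pathogenic	118	88	-
13-199	PKD1	Yes	c.7039delC	p.(Arg2347fs)	Absent	0	Definitely pathogenic	34	32	-
12-628	PKD1	Yes	c.2180T>C	p.(Leu727Pro)	Absent	0	Highly likely pathogenic	20	8	-
08-258	PKD1	Yes	c.7925C>T	p.(Arg2639*)	Present	5	Definitely pathogenic	28	14	-
10-484	PKD1	No	c.12010C>T	p.(Gln4004*)	Present	4	Definitely pathogenic	26	38	-
13-102	-	-	-	-	-	-	-	-	-	-
07-335	-	-	-	-	-	-	-	-	-	-
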