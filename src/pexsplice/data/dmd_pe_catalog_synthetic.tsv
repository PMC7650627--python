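# Curated catalog of 42 reported dystrophin pseudoexons (PEs) and the
# class/mechanism/poison annotation of each, as summarized from the
# dystrophinopathy literature. SYNTHETIC PLACEHOLDERS: genomic
# coordinates, most variant positions, ptc_offset and conservation_mean
# values are synthetic stand-ins (the source curation's appendix-level
# detail is not redistributed here); PE ids, activating-variant classes,
# mechanism groups and poison flags follow the published summary.
pe_id	chrom	start	end	strand	mechanism	variants	variant_class	phenotype	ptc_offset	conservation_mean
PE1	chrX	100000	100092	-	new_ss	g.97501A>G	snv	DMD/BMD		0.50
PE2	chrX	105092	105196	-	new_ss	g.102594A>G	snv	DMD/BMD		0.50
PE3	chrX	110196	110312	-	new_ESE	c.94-78858C>G;c.94-78836T>G	snv	DMD/BMD		0.50
PE4	chrX	115312	115440	-	new_ss	g.112816A>G	snv	DMD/BMD		0.50
PE5	chrX	120440	120520	-	new_ss	c.650-39575A>C;c.650-39498A>G	snv	DMD/BMD		0.50
PE6	chrX	125520	125612	-	new_ss	g.123026A>G	snv	DMD/BMD		0.50
PE7	chrX	130612	130716	-	new_ss	g.128119A>G	snv	DMD/BMD		0.50
PE8	chrX	135716	135832	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE9	chrX	140832	140960	-	new_ss	g.138341A>G	snv	DMD/BMD		0.50
PE10	chrX	145960	146040	-	new_ss	g.143470A>G	snv	DMD/BMD		0.50
PE11	chrX	151040	151132	-	new_ESE	g.148551A>G	snv	DMD/BMD		0.50
PE12	chrX	156132	156236	-	new_ss	g.153644A>G	snv	DMD/BMD		0.50
PE13	chrX	161236	161352	-	new_ss	g.158749A>G	snv	DMD/BMD		0.50
PE14	chrX	166352	166480	-	new_ss	g.163866A>G	snv	DMD/BMD		0.50
PE15	chrX	171480	171560	-	new_ESE	g.168995A>G	snv	DMD/BMD		0.50
PE16	chrX	176560	176652	-	new_ss	g.174076A>G	snv	DMD/BMD		0.50
PE17	chrX	181652	181756	-	new_ss	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE18	chrX	186756	186872	-	new_ESE	g.184274A>G	snv	DMD/BMD		0.50
PE19	chrX	191872	192000	-	new_ss	g.189391A>G	snv	DMD/BMD		0.50
PE20	chrX	197000	197080	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE21	chrX	202080	202172	-	new_ESE	g.199080_199097del	small_deletion	DMD/BMD		0.50
PE22	chrX	207172	207276	-	new_ss	g.204694A>G	snv	DMD/BMD	12	3.50
PE23	chrX	212276	212392	-	new_ss	g.209799A>G	snv	DMD/BMD	12	3.50
PE24	chrX	217392	217520	-	new_ss	g.214916A>G	snv	DMD/BMD		0.50
PE25	chrX	222520	222600	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE26	chrX	227600	227692	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE27	chrX	232692	232796	-	new_ss	g.230219A>G	snv	DMD/BMD		0.50
PE28	chrX	237796	237912	-	new_ss	g.235324A>G	snv	DMD/BMD		0.50
PE29	chrX	242912	243040	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE30	chrX	248040	248120	-	new_ss	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE31	chrX	253120	253212	-	new_ss	g.250651A>G	snv	DMD/BMD		0.50
PE32	chrX	258212	258316	-	new_ss	g.255744A>G	snv	DMD/BMD		0.50
PE33	chrX	263316	263432	-	new_ss	g.260849A>G	snv	DMD/BMD	12	3.50
PE34	chrX	268432	268560	-	new_ESE	complex intronic rearrangement (descriptive)	large_rearrangement	DMD/BMD		0.50
PE35	chrX	273560	273640	-	new_ss	g.271095A>G	snv	DMD/BMD		0.50
PE36	chrX	278640	278732	-	new_ss	g.276176A>G	snv	DMD/BMD	12	3.50
PE37	chrX	283732	283836	-	new_ss	g.281269A>G	snv	DMD/BMD	12	3.50
PE38	chrX	288836	288952	-	new_ss	g.286374A>G	snv	DMD/BMD		0.50
PE39	chrX	293952	294080	-	new_ss	g.291491A>G	snv	DMD/BMD		0.50
PE40	chrX	299080	299160	-	new_ss	g.296620A>G	snv	DMD/BMD		0.50
PE41	chrX	304160	304252	-	new_ss	g.301701A>G	snv	DMD/BMD		0.50
PE42	chrX	309252	309356	-	new_ss	g.306794A>G	snv	DMD/BMD		0.50
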