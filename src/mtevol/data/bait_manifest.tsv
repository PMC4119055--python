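# E. coli MTase bait families: 34 RNA MTase families (the bifunctional
# RlmK/L entry counts as two) plus 9 non-RNA MTase families.
# columns: family, alt_names, substrate, modification, mtase_class, accession, counts_as, function
family	alt_names	substrate	modification	mtase_class	accession	counts_as	function
RlmA	RrmA;YebH	23S rRNA	m1G745	Class I	P36999	1	23S rRNA
RlmB	YfjH	23S rRNA	Gm2251	Class IV	P63177	1	23S rRNA
RlmC	RumB;YbjF	23S rRNA	m5U747	Class I	P75817	1	23S rRNA
RlmD	RumA;YgcA	23S rRNA	m5U1939	Class I	P55135	1	23S rRNA
RlmE	FtsJ;MrsF;RrmJ	23S rRNA	Um2552	Class IV	P0C0R7	1	23S rRNA
RlmF	YbiN	23S rRNA	m6A1618	Class I	P75782	1	23S rRNA
RlmG	YgjO	23S rRNA	m2G1835	Class I	P42596	1	23S rRNA
RlmH	YbeA	23S rRNA	m3Y1915	Class IV	P0A8I8	1	23S rRNA
RlmI	YccW	23S rRNA	m5C1962	Class I	P75876	1	23S rRNA
RlmJ	YhiR	23S rRNA	m6A2030	Class I	P37634	1	23S rRNA
RlmK/L	YcbY	23S rRNA	m7G2069/m2G2445	Class I	P75864	2	23S rRNA
RlmM	YgdE	23S rRNA	Cm2498	Class I	P0ADR6	1	23S rRNA
RlmN	YfgB	23S rRNA	m2A2503/m2A37	Radical SAM	P36979	1	23S rRNA
RsmA	KsgA	16S rRNA	m62A1518/m62A1519	Class I	P06992	1	16S rRNA
RsmB	RrmB;YhdB;Sun	16S rRNA	m5C967	Class I	P36929	1	16S rRNA
RsmC	YjjT	16S rRNA	m2G1207	Class I	P39406	1	16S rRNA
RsmD	YhhF	16S rRNA	m2G966	Class I	P0ADX9	1	16S rRNA
RsmE	YggJ	16S rRNA	m3U1498	Class IV	P0AGL7	1	16S rRNA
RsmF	YebU	16S rRNA	m5C1407	Class I	P76273	1	16S rRNA
RsmG	GidB	16S rRNA	m7G527	Class I	P0A6U5	1	16S rRNA
RsmH	MraW;YabC	16S rRNA	m4C1402	Class I	P60390	1	16S rRNA
RsmI	YraL	16S rRNA	Cm1402	Class I	P67087	1	16S rRNA
RsmJ	YhiQ	16S rRNA	m2G1516	Class I	P68567	1	16S rRNA
TrmA	RumT	tRNA/tmRNA	m5U54/m5U341	Class I	P23003	1	tRNA
TrmB	YggH	tRNA	m7G46	Class I	P0A8I5	1	tRNA
TrmD	TrmD	tRNA	m1G37	Class IV	P0A873	1	tRNA
TrmH	SpoU	tRNA	Gm18	Class IV	P0AGJ2	1	tRNA
TrmJ	YfhQ	tRNA	Um32/Cm32	Class IV	P0AE01	1	tRNA
TrmL	YibK	tRNA	Um34/Cm34	Class IV	P0AGJ7	1	tRNA
TrmN6	YfiC	tRNA	m6A37	Class I	P31825	1	tRNA
MnmC	YfcK;TrmC	tRNA	mnm5U	Class I	P77182	1	tRNA
CmoA	YecO	tRNA	cmo5U	Class I	P76290	1	tRNA
CmoB	YecP	tRNA	cmo5U	Class I	P76291	1	tRNA
BioB	-	non-RNA	biotin synthesis	Radical SAM	NA	1	cofactor/vitamin
BioC	-	non-RNA	biotin synthesis	Class I	NA	1	cofactor/vitamin
PrmA	-	non-RNA	ribosomal protein L11	Class I	NA	1	ribosomal protein
PrmB	-	non-RNA	ribosomal protein L3	Class I	NA	1	ribosomal protein
PrmC	HemK	non-RNA	release factor	Class I	NA	1	ribosomal protein
SmtA	-	non-RNA	unknown	Class I	NA	1	unknown
Tam	-	non-RNA	trans-aconitate	Class I	NA	1	unknown
UbiE	-	non-RNA	ubiquinone synthesis	Class I	NA	1	cofactor/vitamin
UbiG	-	non-RNA	ubiquinone synthesis	Class I	NA	1	cofactor/vitamin
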