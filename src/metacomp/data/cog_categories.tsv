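family_id	category_id	category_label
COG0081	J	Translation, ribosomal structure and biogenesis
COG0244	J	Translation, ribosomal structure and biogenesis
COG1094	A	RNA processing and modification
COG5108	A	RNA processing and modification
COG0085	K	Transcription
COG0568	K	Transcription
COG0187	L	Replication, recombination and repair
COG0550	L	Replication, recombination and repair
COG2036	B	Chromatin structure and dynamics
COG5262	B	Chromatin structure and dynamics
COG0206	D	Cell cycle control, cell division, chromosome partitioning
COG1196	D	Cell cycle control, cell division, chromosome partitioning
COG5096	Y	Nuclear structure
COG5259	Y	Nuclear structure
COG1131	V	Defense mechanisms
COG1132	V	Defense mechanisms
COG1136	V	Defense mechanisms
COG2274	V	Defense mechanisms
COG0642	T	Signal transduction mechanisms
COG0784	T	Signal transduction mechanisms
COG0768	M	Cell wall/membrane/envelope biogenesis
COG0744	M	Cell wall/membrane/envelope biogenesis
COG1291	N	Cell motility
COG1344	N	Cell motility
COG5277	Z	Cytoskeleton
COG5069	Z	Cytoskeleton
COG1450	W	Extracellular structures
COG4964	W	Extracellular structures
COG0542	U	Intracellular trafficking, secretion, and vesicular transport
COG1459	U	Intracellular trafficking, secretion, and vesicular transport
COG0265	O	Posttranslational modification, protein turnover, chaperones
COG0459	O	Posttranslational modification, protein turnover, chaperones
COG0039	C	Energy production and conversion
COG0538	C	Energy production and conversion
COG0366	G	Carbohydrate transport and metabolism
COG1455	G	Carbohydrate transport and metabolism
COG0014	E	Amino acid transport and metabolism
COG0498	E	Amino acid transport and metabolism
COG0104	F	Nucleotide transport and metabolism
COG0503	F	Nucleotide transport and metabolism
COG0117	H	Coenzyme transport and metabolism
COG0452	H	Coenzyme transport and metabolism
COG0183	I	Lipid transport and metabolism
COG0764	I	Lipid transport and metabolism
COG0168	P	Inorganic ion transport and metabolism
COG0598	P	Inorganic ion transport and metabolism
COG0500	Q	Secondary metabolites biosynthesis, transport and catabolism
COG2124	Q	Secondary metabolites biosynthesis, transport and catabolism
COG0457	R	General function prediction only
COG0790	R	General function prediction only
COG0398	S	Function unknown
COG0433	S	Function unknown
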