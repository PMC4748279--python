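lincrna_id	degree	go_id	go_name
XLOC_029375	19	GO:0000304	response to singlet oxygen
XLOC_071313	57	GO:0080027	response to herbivore
XLOC_035144	43	GO:0080027	response to herbivore
XLOC_073642	124	GO:0009991	response to extracellular stimulus
XLOC_030020	83	GO:0009991	response to extracellular stimulus
XLOC_059443	125	GO:0009787	regulation of abscisic acid-activated signaling pathway
XLOC_027543	94	GO:0009787	regulation of abscisic acid-activated signaling pathway
XLOC_045455	76	GO:0009787	regulation of abscisic acid-activated signaling pathway
XLOC_043084	75	GO:0009787	regulation of abscisic acid-activated signaling pathway
XLOC_074955	48	GO:0009787	regulation of abscisic acid-activated signaling pathway
XLOC_037969	22	GO:0006656	phosphatidylcholine biosynthetic process
XLOC_045400	32	GO:0080148	negative regulation of response to water deprivation
XLOC_019886	241	GO:0006378	mRNA polyadenylation
XLOC_053044	198	GO:0006378	mRNA polyadenylation
XLOC_002113	173	GO:0006378	mRNA polyadenylation
XLOC_068645	160	GO:0006378	mRNA polyadenylation
XLOC_047346	143	GO:0006378	mRNA polyadenylation
XLOC_031943	126	GO:0006378	mRNA polyadenylation
XLOC_016946	110	GO:0006378	mRNA polyadenylation
XLOC_069348	88	GO:0006378	mRNA polyadenylation
XLOC_049097	65	GO:0006378	mRNA polyadenylation
XLOC_058915	120	GO:0006869	lipid transport
XLOC_030698	102	GO:0006869	lipid transport
XLOC_024209	80	GO:0006869	lipid transport
XLOC_077187	75	GO:0006869	lipid transport
XLOC_026516	60	GO:0006869	lipid transport
XLOC_010433	22	GO:0008610	lipid biosynthetic process
XLOC_025812	60	GO:0070652	HAUS complex
XLOC_054892	41	GO:0070652	HAUS complex
XLOC_027447	27	GO:0070652	HAUS complex
XLOC_076778	26	GO:0070652	HAUS complex
XLOC_014220	34	GO:0047940	glucuronokinase activity
XLOC_061908	23	GO:0006680	glucosylceramide catabolic process
XLOC_048059	40	GO:0017004	cytochrome complex assembly
XLOC_063523	144	GO:0071368	cellular response to cytokinin stimulus
XLOC_040486	66	GO:0071368	cellular response to cytokinin stimulus
XLOC_007198	48
XLOC_067119	26
XLOC_026094	25
XLOC_072903	19
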