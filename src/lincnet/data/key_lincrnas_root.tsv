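lincrna_id	degree	go_id	go_name
XLOC_026030	60	GO:0016036	cellular response to phosphate starvation
XLOC_051315	51	GO:0016036	cellular response to phosphate starvation
XLOC_010233	48	GO:0016036	cellular response to phosphate starvation
XLOC_054628	28	GO:0016036	cellular response to phosphate starvation
XLOC_049577	114	GO:0009250	glucan biosynthetic process
XLOC_077203	100	GO:0009250	glucan biosynthetic process
XLOC_055397	60	GO:0009250	glucan biosynthetic process
XLOC_031943	59	GO:0009250	glucan biosynthetic process
XLOC_062736	56	GO:0009250	glucan biosynthetic process
XLOC_058915	52	GO:0009250	glucan biosynthetic process
XLOC_027868	45	GO:0009250	glucan biosynthetic process
XLOC_044456	33	GO:0009250	glucan biosynthetic process
XLOC_003338	90	GO:0047940	glucuronokinase activity
XLOC_018392	63	GO:0047940	glucuronokinase activity
XLOC_058089	58	GO:0047940	glucuronokinase activity
XLOC_027543	37	GO:0047940	glucuronokinase activity
XLOC_037399	28	GO:0047940	glucuronokinase activity
XLOC_014220	27	GO:0047940	glucuronokinase activity
XLOC_041683	22	GO:0047940	glucuronokinase activity
XLOC_018843	18	GO:0070652	HAUS complex
XLOC_067881	18	GO:0070652	HAUS complex
XLOC_020260	78	GO:0006848	pyruvate transport
XLOC_055176	68	GO:0006848	pyruvate transport
XLOC_030698	56	GO:0006848	pyruvate transport
XLOC_032273	55	GO:0006848	pyruvate transport
XLOC_067770	47	GO:0006848	pyruvate transport
XLOC_026516	40	GO:0006848	pyruvate transport
XLOC_040629	39	GO:0006848	pyruvate transport
XLOC_025619	31	GO:0090322	regulation of superoxide metabolic process
XLOC_059443	40	GO:0002237	response to molecule of bacterial origin
XLOC_008468	26	GO:0002237	response to molecule of bacterial origin
XLOC_001099	19	GO:0002237	response to molecule of bacterial origin
XLOC_030020	40	GO:0080150	S-adenosyl-L-methionine: benzoic acid carboxyl methyl transferase activity
XLOC_056226	33	GO:0080150	S-adenosyl-L-methionine: benzoic acid carboxyl methyl transferase activity
XLOC_049097	28	GO:0000124	SAGA complex
XLOC_001874	52	GO:0005774	vacuolar membrane
XLOC_004428	45
XLOC_012843	31
XLOC_037613	27
XLOC_045461	26
XLOC_053440	26
XLOC_037810	25
XLOC_006373	21
XLOC_009491	20
XLOC_076889	20
XLOC_063523	19
XLOC_045455	18
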