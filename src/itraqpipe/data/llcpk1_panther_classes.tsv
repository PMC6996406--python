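# PANTHER Protein Class membership for the 128 classified proteins of a
# porcine (Sus scrofa) proximal-tubule cell (LLC PK-1) iTRAQ proteome,
# against the PANTHER 12.0 Sus scrofa reference list (21324 proteins).
# reference_total=21324
# input_total=128
class_id	class_name	reference_count	observed
PC00228	Tubulin	20	4
PC00120	Hydratase	16	3
PC00202	Ribosomal protein	241	23
PC00092	Dehydrogenase	234	11
PC00135	Isomerase	131	6
PC00031	RNA binding protein	681	24
PC00176	Oxidoreductase	540	19
PC00041	Actin family cytoskeletal protein	313	10
PC00085	Cytoskeletal protein	660	15
PC00171	Nucleic acid binding	2031	28
Unclassified	Unclassified	11800	31
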