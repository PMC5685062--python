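pathway_a	pathway_b	occurrence_count
EIF2 signaling	LXR/RXR activation	3
Glutamate receptor signaling	Mitochondrial dysfunction	3
EIF2 signaling	iNOS signaling	3
IL-1 signaling	Mitochondrial dysfunction	3
CCR5 signaling in macrophages	Mitochondrial dysfunction	3
EIF2 signaling	Hepatic fibrosis/hepatic stellate cell activation	3
EIF2 signaling	MIF regulation of innate immunity	3
G protein signaling mediated by Tubby	Mitochondrial dysfunction	4
G beta gamma signaling	Mitochondrial dysfunction	4
SAPK/JNK signaling	Mitochondrial dysfunction	5
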