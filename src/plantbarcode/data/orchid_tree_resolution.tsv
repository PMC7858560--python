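sample_id	marker	level	resolved_name
G1	ITS	SPECIES	Platanthera chlorantha
G1	accD	UNRESOLVED	
G1	rpoB	SPECIES	Platanthera chlorantha
G3	ITS	SPECIES	Orchis militaris
G3	accD	UNRESOLVED	
G3	rpoB	UNRESOLVED	
G4	ITS	SPECIES	Orchis militaris
G4	accD	UNRESOLVED	
G4	rpoB	UNRESOLVED	
G5	ITS	SPECIES	Orchis adenocheila
G5	accD	UNRESOLVED	
G5	rpoB	UNRESOLVED	
G6	ITS	SPECIES	Orchis simia
G6	accD	UNRESOLVED	
G6	rpoB	UNRESOLVED	
G7	ITS	SPECIES	Anacamptis pyramidalis
G7	accD	UNRESOLVED	
G7	rpoB	UNRESOLVED	
G9	ITS	SPECIES	Anacamptis pyramidalis
G9	accD	UNRESOLVED	
G9	rpoB	UNRESOLVED	
G10	ITS	SPECIES	Orchis mascula
G10	accD	UNRESOLVED	
G10	rpoB	SPECIES	Orchis mascula
G11	ITS	SPECIES	Orchis mascula
G11	accD	UNRESOLVED	
G11	rpoB	UNRESOLVED	
G12	ITS	SPECIES	Anacamptis pyramidalis
G12	accD	UNRESOLVED	
G12	rpoB	UNRESOLVED	
G14	ITS	SPECIES	Anacamptis pyramidalis
G14	accD	UNRESOLVED	
G14	rpoB	UNRESOLVED	
G15	ITS	GENUS_ONLY	Cephalanthera sp.
G15	accD	GENUS_ONLY	Cephalanthera sp.
G15	rpoB	GENUS_ONLY	Cephalanthera sp.
G16	ITS	SPECIES	Platanthera chlorantha
G16	accD	UNRESOLVED	
G16	rpoB	SPECIES	Platanthera chlorantha
G17	ITS	SPECIES	Ophrys sphegodes
G17	accD	SPECIES	Orchis simia
G17	rpoB	GENUS_ONLY	Ophrys sp.
G18	ITS	SPECIES	Gymnadenia conopsea
G18	accD	SPECIES	Gymnadenia conopsea
G18	rpoB	SPECIES	Gymnadenia conopsea
G19	ITS	SPECIES	Dactylorhiza maculata
G19	accD	GENUS_ONLY	Dactylorhiza sp.
G19	rpoB	GENUS_ONLY	Dactylorhiza sp.
G27	ITS	SPECIES	Orchis militaris
G27	accD	UNRESOLVED	
G27	rpoB	UNRESOLVED	
G29	ITS	SPECIES	Orchis militaris
G29	accD	UNRESOLVED	
G29	rpoB	UNRESOLVED	
G31	ITS	SPECIES	Orchis militaris
G31	accD	UNRESOLVED	
G31	rpoB	UNRESOLVED	
G32	ITS	SPECIES	Orchis militaris
G32	accD	UNRESOLVED	
G32	rpoB	UNRESOLVED	
G35	ITS	SPECIES	Orchis militaris
G35	accD	UNRESOLVED	
G35	rpoB	UNRESOLVED	
G36	ITS	SPECIES	Orchis militaris
G36	accD	UNRESOLVED	
G36	rpoB	UNRESOLVED	
G37	ITS	SPECIES	Orchis adenocheila
G37	accD	SPECIES	Orchis purpurea
G37	rpoB	UNRESOLVED	
G38	ITS	SPECIES	Orchis adenocheila
G38	accD	SPECIES	Orchis purpurea
G38	rpoB	UNRESOLVED	
G13	rpoB	UNRESOLVED	
G8	rpoB	UNRESOLVED	
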