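sample_id	marker	outcome	assigned_species
G1	ITS	AMBIGUOUS_TOP	
G1	accD	AMBIGUOUS_TOP	
G1	rpoB	CORRECT	Platanthera chlorantha
G3	ITS	CORRECT	Orchis militaris
G3	accD	AMBIGUOUS_TOP	
G3	rpoB	BELOW_THRESHOLD	
G4	ITS	CORRECT	Orchis militaris
G4	accD	AMBIGUOUS_TOP	
G4	rpoB	BELOW_THRESHOLD	
G5	ITS	CORRECT	Orchis adenocheila
G5	accD	BELOW_THRESHOLD	
G5	rpoB	BELOW_THRESHOLD	
G6	ITS	CORRECT	Orchis simia
G6	accD	AMBIGUOUS_TOP	
G6	rpoB	BELOW_THRESHOLD	
G7	ITS	CORRECT	Anacamptis pyramidalis
G7	accD	BELOW_THRESHOLD	
G7	rpoB	BELOW_THRESHOLD	
G8	rpoB	BELOW_THRESHOLD	
G9	ITS	CORRECT	Anacamptis pyramidalis
G9	accD	BELOW_THRESHOLD	
G9	rpoB	BELOW_THRESHOLD	
G10	ITS	CORRECT	Orchis mascula
G10	accD	AMBIGUOUS_TOP	
G10	rpoB	BELOW_THRESHOLD	
G11	ITS	CORRECT	Orchis mascula
G11	accD	AMBIGUOUS_TOP	
G11	rpoB	BELOW_THRESHOLD	
G12	ITS	CORRECT	Anacamptis pyramidalis
G12	accD	BELOW_THRESHOLD	
G12	rpoB	BELOW_THRESHOLD	
G13	rpoB	BELOW_THRESHOLD	
G14	ITS	CORRECT	Anacamptis pyramidalis
G14	accD	BELOW_THRESHOLD	
G14	rpoB	BELOW_THRESHOLD	
G15	ITS	AMBIGUOUS_TOP	
G15	accD	AMBIGUOUS_TOP	
G15	rpoB	AMBIGUOUS_TOP	
G16	ITS	AMBIGUOUS_TOP	
G16	accD	AMBIGUOUS_TOP	
G16	rpoB	CORRECT	Platanthera chlorantha
G17	ITS	CORRECT	Ophrys sphegodes
G17	accD	BELOW_THRESHOLD	
G17	rpoB	BELOW_THRESHOLD	
G18	ITS	CORRECT	Gymnadenia conopsea
G18	accD	AMBIGUOUS_TOP	
G18	rpoB	CORRECT	Gymnadenia conopsea
G19	ITS	AMBIGUOUS_TOP	
G19	accD	CORRECT	Dactylorhiza saccifera
G19	rpoB	AMBIGUOUS_TOP	
G27	ITS	CORRECT	Orchis militaris
G27	accD	BELOW_THRESHOLD	
G27	rpoB	BELOW_THRESHOLD	
G29	ITS	CORRECT	Orchis militaris
G29	accD	AMBIGUOUS_TOP	
G29	rpoB	BELOW_THRESHOLD	
G31	ITS	CORRECT	Orchis militaris
G31	accD	BELOW_THRESHOLD	
G31	rpoB	BELOW_THRESHOLD	
G32	ITS	CORRECT	Orchis militaris
G32	accD	BELOW_THRESHOLD	
G32	rpoB	BELOW_THRESHOLD	
G35	ITS	CORRECT	Orchis militaris
G35	accD	BELOW_THRESHOLD	
G35	rpoB	BELOW_THRESHOLD	
G36	ITS	CORRECT	Orchis militaris
G36	accD	AMBIGUOUS_TOP	
G36	rpoB	BELOW_THRESHOLD	
G37	ITS	CORRECT	Orchis adenocheila
G37	accD	BELOW_THRESHOLD	
G37	rpoB	BELOW_THRESHOLD	
G38	ITS	CORRECT	Orchis adenocheila
G38	accD	BELOW_THRESHOLD	
G38	rpoB	BELOW_THRESHOLD	
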