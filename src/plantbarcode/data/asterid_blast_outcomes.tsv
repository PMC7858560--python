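sample_id	marker	outcome	assigned_species
P1	ITS	CORRECT	Centaurea nogmovii
P1	accD	AMBIGUOUS_TOP	
P1	rpoB	CORRECT	Carthamus tinctorius
P2	ITS	BELOW_THRESHOLD	
P2	accD	AMBIGUOUS_TOP	
P2	rpoB	CORRECT	Carthamus tinctorius
P3	ITS	CORRECT	Psephellus hadimensis
P3	accD	AMBIGUOUS_TOP	
P3	rpoB	CORRECT	Carthamus tinctorius
P4	ITS	CORRECT	Centaurea nogmovii
P4	accD	AMBIGUOUS_TOP	
P4	rpoB	CORRECT	Carthamus tinctorius
P5	ITS	CORRECT	Centaurea nogmovii
P5	accD	AMBIGUOUS_TOP	
P5	rpoB	CORRECT	Carthamus tinctorius
P6	ITS	CORRECT	Psephellus hadimensis
P6	accD	AMBIGUOUS_TOP	
P6	rpoB	CORRECT	Carthamus tinctorius
P7	ITS	CORRECT	Centaurea nogmovii
P7	accD	AMBIGUOUS_TOP	
P7	rpoB	CORRECT	Carthamus tinctorius
P8	ITS	CORRECT	Centaurea nogmovii
P8	accD	AMBIGUOUS_TOP	
P8	rpoB	CORRECT	Carthamus tinctorius
P9	ITS	CORRECT	Centaurea nogmovii
P9	accD	AMBIGUOUS_TOP	
P9	rpoB	CORRECT	Carthamus tinctorius
A1	ITS	AMBIGUOUS_TOP	
A1	accD	AMBIGUOUS_TOP	
A1	rpoB	CORRECT	Leucanthemum vulgare
A2	ITS	BELOW_THRESHOLD	
A2	accD	AMBIGUOUS_TOP	
A2	rpoB	CORRECT	Leucanthemum vulgare
A3	ITS	AMBIGUOUS_TOP	
A3	accD	AMBIGUOUS_TOP	
A3	rpoB	CORRECT	Leucanthemum vulgare
A4	ITS	BELOW_THRESHOLD	
A4	accD	AMBIGUOUS_TOP	
A4	rpoB	CORRECT	Leucanthemum vulgare
A5	ITS	AMBIGUOUS_TOP	
A5	accD	AMBIGUOUS_TOP	
A5	rpoB	CORRECT	Leucanthemum vulgare
A6	ITS	BELOW_THRESHOLD	
A6	accD	AMBIGUOUS_TOP	
A6	rpoB	CORRECT	Leucanthemum vulgare
A7	ITS	CORRECT	Bellis pusilla
A7	accD	BELOW_THRESHOLD	
A7	rpoB	AMBIGUOUS_TOP	
A8	ITS	CORRECT	Bellis pusilla
A8	accD	BELOW_THRESHOLD	
A8	rpoB	AMBIGUOUS_TOP	
A9	ITS	CORRECT	Hypochaeris radicata
A9	accD	AMBIGUOUS_TOP	
A9	rpoB	AMBIGUOUS_TOP	
A10	ITS	CORRECT	Leontodon hispidus
A10	accD	AMBIGUOUS_TOP	
A10	rpoB	AMBIGUOUS_TOP	
A11	ITS	AMBIGUOUS_TOP	
A11	accD	BELOW_THRESHOLD	
A11	rpoB	AMBIGUOUS_TOP	
A12	ITS	CORRECT	Tanacetum coccineum
A12	accD	AMBIGUOUS_TOP	
A12	rpoB	AMBIGUOUS_TOP	
A13	ITS	CORRECT	Senecio vernalis
A13	accD	AMBIGUOUS_TOP	
A13	rpoB	AMBIGUOUS_TOP	
A14	ITS	CORRECT	Symphyotrichum novae-angliae
A14	accD	AMBIGUOUS_TOP	
A14	rpoB	AMBIGUOUS_TOP	
A15	ITS	BELOW_THRESHOLD	
A15	accD	AMBIGUOUS_TOP	
A15	rpoB	AMBIGUOUS_TOP	
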