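sample_id	marker	level	resolved_name
P1	ITS	GENUS_ONLY	Centaurea sp.
P1	accD	GENUS_ONLY	Psephellus sp.
P1	rpoB	GENUS_ONLY	Psephellus sp.
P2	ITS	UNRESOLVED	
P2	accD	GENUS_ONLY	Psephellus sp.
P2	rpoB	GENUS_ONLY	Psephellus sp.
P3	ITS	SPECIES	Psephellus hadimensis
P3	accD	GENUS_ONLY	Psephellus sp.
P3	rpoB	GENUS_ONLY	Psephellus sp.
P4	ITS	GENUS_ONLY	Centaurea sp.
P4	accD	GENUS_ONLY	Psephellus sp.
P4	rpoB	GENUS_ONLY	Psephellus sp.
P5	ITS	GENUS_ONLY	Centaurea sp.
P5	accD	GENUS_ONLY	Psephellus sp.
P5	rpoB	GENUS_ONLY	Psephellus sp.
P6	ITS	SPECIES	Psephellus hadimensis
P6	accD	GENUS_ONLY	Psephellus sp.
P6	rpoB	GENUS_ONLY	Psephellus sp.
P7	ITS	SPECIES	Centaurea nogmovii
P7	accD	GENUS_ONLY	Psephellus sp.
P7	rpoB	GENUS_ONLY	Psephellus sp.
P8	ITS	SPECIES	Centaurea nogmovii
P8	accD	GENUS_ONLY	Psephellus sp.
P8	rpoB	GENUS_ONLY	Psephellus sp.
P9	ITS	GENUS_ONLY	Centaurea sp.
P9	accD	GENUS_ONLY	Psephellus sp.
P9	rpoB	GENUS_ONLY	Psephellus sp.
A1	ITS	GENUS_ONLY	Leucanthemum sp.
A1	accD	GENUS_ONLY	Leucanthemum sp.
A1	rpoB	SPECIES	Leucanthemum vulgare
A2	ITS	GENUS_ONLY	Leucanthemum sp.
A2	accD	GENUS_ONLY	Leucanthemum sp.
A2	rpoB	SPECIES	Leucanthemum vulgare
A3	ITS	GENUS_ONLY	Leucanthemum sp.
A3	accD	GENUS_ONLY	Leucanthemum sp.
A3	rpoB	SPECIES	Leucanthemum vulgare
A4	ITS	UNRESOLVED	
A4	accD	UNRESOLVED	
A4	rpoB	SPECIES	Leucanthemum vulgare
A5	ITS	UNRESOLVED	
A5	accD	GENUS_ONLY	Leucanthemum sp.
A5	rpoB	SPECIES	Leucanthemum vulgare
A6	ITS	GENUS_ONLY	Leucanthemum sp.
A6	accD	GENUS_ONLY	Leucanthemum sp.
A6	rpoB	SPECIES	Leucanthemum vulgare
A7	ITS	SPECIES	Bellis pusilla
A7	accD	UNRESOLVED	
A7	rpoB	SPECIES	Bellis perennis
A8	ITS	GENUS_ONLY	Bellis sp.
A8	accD	UNRESOLVED	
A8	rpoB	SPECIES	Bellis perennis
A9	ITS	GENUS_ONLY	Taraxacum sp.
A9	accD	GENUS_ONLY	Taraxacum sp.
A9	rpoB	GENUS_ONLY	Taraxacum sp.
A10	ITS	SPECIES	Leontodon hispidus
A10	accD	UNRESOLVED	
A10	rpoB	UNRESOLVED	
A11	ITS	SPECIES	Taraxacum officinale
A11	accD	SPECIES	Taraxacum officinale
A11	rpoB	GENUS_ONLY	Taraxacum sp.
A12	ITS	SPECIES	Tanacetum coccineum
A12	accD	UNRESOLVED	
A12	rpoB	UNRESOLVED	
A13	ITS	SPECIES	Senecio vernalis
A13	accD	GENUS_ONLY	Senecio sp.
A13	rpoB	GENUS_ONLY	Senecio sp.
A14	ITS	UNRESOLVED	
A14	accD	GENUS_ONLY	Aster sp.
A14	rpoB	SPECIES	Aster hypoleucus
A15	ITS	UNRESOLVED	
A15	accD	UNRESOLVED	
A15	rpoB	SPECIES	Bellis perennis
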