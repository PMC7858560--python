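sample_id	marker	amplified	sequenced
P1	ITS	x	x
P1	rpoB	x	x
P1	accD	x	x
P2	ITS	x	x
P2	rpoB	x	x
P2	accD	x	x
P3	ITS	x	x
P3	rpoB	x	x
P3	accD	x	x
P4	ITS	x	x
P4	rpoB	x	x
P4	accD	x	x
P5	ITS	x	x
P5	rpoB	x	x
P5	accD	x	x
P6	ITS	x	x
P6	rpoB	x	x
P6	accD	x	x
P7	ITS	x	x
P7	rpoB	x	x
P7	accD	x	x
P8	ITS	x	x
P8	rpoB	x	x
P8	accD	x	x
P9	ITS	x	x
P9	rpoB	x	x
P9	accD	x	x
A1	ITS	x	x
A1	rpoB	x	x
A1	accD	x	x
A2	ITS	x	x
A2	rpoB	x	x
A2	accD	x	x
A3	ITS	x	x
A3	rpoB	x	x
A3	accD	x	x
A4	ITS	x	x
A4	rpoB	x	x
A4	accD	x	x
A5	ITS	x	x
A5	rpoB	x	x
A5	accD	x	x
A6	ITS	x	x
A6	rpoB	x	x
A6	accD	x	x
A7	ITS	x	x
A7	rpoB	x	x
A7	accD	x	x
A8	ITS	x	x
A8	rpoB	x	x
A8	accD	x	x
A9	ITS	x	x
A9	rpoB	x	x
A9	accD	x	x
A10	ITS	x	x
A10	rpoB	x	x
A10	accD	x	x
A11	ITS	x	x
A11	rpoB	x	x
A11	accD	x	x
A12	ITS	x	x
A12	rpoB	x	x
A12	accD	x	x
A13	ITS	x	x
A13	rpoB	x	x
A13	accD	x	x
A14	ITS	x	x
A14	rpoB	x	x
A14	accD	x	x
A15	ITS	x	x
A15	rpoB	x	x
A15	accD	x	x
Centaurea_trinervia_Herbarium_18066	ITS	x	x
Centaurea_trinervia_Herbarium_18066	rpoB	x	x
Centaurea_trinervia_Herbarium_18066	accD	x	x
Centaurea_trinervia_Herbarium_18067	ITS	x	x
Centaurea_trinervia_Herbarium_18067	rpoB	x	x
Centaurea_trinervia_Herbarium_18067	accD	x	x
Psephellus_hymenolepis_Herbarium_22220	ITS	x	x
Psephellus_hymenolepis_Herbarium_22220	rpoB	x	x
Psephellus_hymenolepis_Herbarium_22220	accD	x	x
Psephellus_daghestanicus_Herbarium_22262	ITS	x	x
Psephellus_daghestanicus_Herbarium_22262	rpoB	x	x
Psephellus_daghestanicus_Herbarium_22262	accD	x	x
Psephellus_dealbatus_Herbarium_22213	ITS	x	x
Psephellus_dealbatus_Herbarium_22213	rpoB	x	x
Psephellus_dealbatus_Herbarium_22213	accD	x	x
Psephellus_intergrifolius_Herbarium_18082	ITS	x	x
Psephellus_intergrifolius_Herbarium_18082	rpoB	x	x
Psephellus_intergrifolius_Herbarium_18082	accD	x	x
Psephellus_xantocephalus_Herbarium_18471	ITS	x	x
Psephellus_xantocephalus_Herbarium_18471	rpoB	x	x
Psephellus_xantocephalus_Herbarium_18471	accD	x	x
Psephellus_transcaucasicus_Herbarium_22234	ITS	x	x
Psephellus_transcaucasicus_Herbarium_22234	rpoB	x	x
Psephellus_transcaucasicus_Herbarium_22234	accD	x	x
Psephellus_transcaucasicus_Herbarium_22256	ITS	x	x
Psephellus_transcaucasicus_Herbarium_22256	rpoB	x	x
Psephellus_transcaucasicus_Herbarium_22256	accD	x	x
Pyrethrum_carneum_Herbarium_22357	ITS	x	x
Pyrethrum_carneum_Herbarium_22357	rpoB	x	x
Pyrethrum_carneum_Herbarium_22357	accD	x	x
Taraxacum_officinale_Herbarium_24510	ITS	x	x
Taraxacum_officinale_Herbarium_24510	rpoB	x	x
Taraxacum_officinale_Herbarium_24510	accD	x	x
Senecio_vernalis_Herbarium	ITS	x	x
Senecio_vernalis_Herbarium	rpoB	x	x
Senecio_vernalis_Herbarium	accD	x	x
Bellis_perennis_Herbarium_170015	ITS	x	x
Bellis_perennis_Herbarium_170015	rpoB	x	x
Bellis_perennis_Herbarium_170015	accD	x	x
Centaurea_cheiranthifolius_Herbarium	ITS	x	x
Centaurea_cheiranthifolius_Herbarium	rpoB	x	x
Centaurea_cheiranthifolius_Herbarium	accD	x	x
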