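sample_id	marker	amplified	sequenced
G1	ITS	x	x
G1	rpoB	x	x
G1	accD	x	x
G3	ITS	x	x
G3	rpoB	x	x
G3	accD	x	x
G4	ITS	x	x
G4	rpoB	x	x
G4	accD	x	x
G5	ITS	x	x
G5	rpoB	x	x
G5	accD	x	x
G6	ITS	x	x
G6	rpoB	x	x
G6	accD	x	x
G7	ITS	x	x
G7	rpoB	x	x
G7	accD	x	x
G8	ITS	NO	NO
G8	rpoB	x	x
G8	accD	x	NO
G9	ITS	x	x
G9	rpoB	x	x
G9	accD	x	x
G10	ITS	x	x
G10	rpoB	x	x
G10	accD	x	x
G11	ITS	x	x
G11	rpoB	x	x
G11	accD	x	x
G12	ITS	x	x
G12	rpoB	x	x
G12	accD	x	x
G13	ITS	NO	NO
G13	rpoB	x	x
G13	accD	x	NO
G14	ITS	x	x
G14	rpoB	x	x
G14	accD	x	x
G15	ITS	x	x
G15	rpoB	x	x
G15	accD	x	x
G16	ITS	x	x
G16	rpoB	x	x
G16	accD	x	x
G17	ITS	x	x
G17	rpoB	x	x
G17	accD	x	x
G18	ITS	x	x
G18	rpoB	x	x
G18	accD	x	x
G19	ITS	x	x
G19	rpoB	x	x
G19	accD	x	x
G27	ITS	x	x
G27	rpoB	x	x
G27	accD	x	x
G28	ITS	NO	NO
G28	rpoB	NO	NO
G28	accD	NO	NO
G29	ITS	x	x
G29	rpoB	x	x
G29	accD	x	x
G30	ITS	NO	NO
G30	rpoB	NO	NO
G30	accD	NO	NO
G31	ITS	x	x
G31	rpoB	x	x
G31	accD	x	x
G32	ITS	x	x
G32	rpoB	x	x
G32	accD	x	x
G33	ITS	NO	NO
G33	rpoB	x	NO
G33	accD	x	NO
G34	ITS	NO	NO
G34	rpoB	x	NO
G34	accD	x	NO
G35	ITS	x	x
G35	rpoB	x	x
G35	accD	x	x
G36	ITS	x	x
G36	rpoB	x	x
G36	accD	x	x
G37	ITS	x	x
G37	rpoB	x	x
G37	accD	x	x
G38	ITS	x	x
G38	rpoB	x	x
G38	accD	x	x
Orchis_purpurea_Herbarium_1	ITS	x	x
Orchis_purpurea_Herbarium_1	rpoB	x	x
Orchis_purpurea_Herbarium_1	accD	x	x
Orchis_purpurea_Herbarium_2	ITS	x	x
Orchis_purpurea_Herbarium_2	rpoB	x	x
Orchis_purpurea_Herbarium_2	accD	x	x
Orchis_simia_Herbarium_80873	ITS	x	x
Orchis_simia_Herbarium_80873	rpoB	x	x
Orchis_simia_Herbarium_80873	accD	x	x
Orchis_simia_Herbarium_80876	ITS	x	x
Orchis_simia_Herbarium_80876	rpoB	x	x
Orchis_simia_Herbarium_80876	accD	x	x
Orchis_mascula_Herbarium_80801	ITS	x	x
Orchis_mascula_Herbarium_80801	rpoB	x	x
Orchis_mascula_Herbarium_80801	accD	x	x
Orchis_mascula_Herbarium_80797	ITS	x	x
Orchis_mascula_Herbarium_80797	rpoB	x	x
Orchis_mascula_Herbarium_80797	accD	x	x
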