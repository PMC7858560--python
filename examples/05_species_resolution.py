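"""Tree-based species resolution: the gap versus radiation contrast.

Each accession in turn plays the unknown query; it is SPECIES-resolved
when it joins all references of exactly one species in a monophyletic
group. With interspecific divergence 25x the intraspecific level almost
every query resolves; when the two scales coincide (a recent radiation)
resolution collapses — the contrast between an old, well-differentiated
lineage and a recently radiated one.
"""

import plantbarcode as pb


def resolution_rate(d_intra: float, d_inter: float, seed: int) -> float:
    cfg = pb.SimConfig(
        n_species=10, n_per_species=4, seq_length=800,
        d_intra=d_intra, d_inter=d_inter, seed=seed,
    )
    seqs, truth = pb.simulate_dataset(cfg)
    tree = pb.nj_build(pb.mcl_distance_matrix(seqs))
    species = dict(zip(truth.seq_id, truth.species))
    hits = 0
    for query in seqs.ids:
        refs = {l: s for l, s in species.items() if l != query}
        outcome = pb.resolve_sample(tree, refs, None, query)
        hits += outcome.level is pb.Level.SPECIES
    return hits / len(seqs)


d = 0.00025
gap = sum(resolution_rate(d, 25 * d, s) for s in range(3)) / 3
radiation = sum(resolution_rate(d, d, s) for s in range(3)) / 3
print(f"gap regime (d_inter/d_intra = 25): {gap:.1%} of queries SPECIES-resolved")
print(f"radiation regime (d_inter = d_intra): {radiation:.1%} of queries SPECIES-resolved")
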