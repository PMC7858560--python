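"""Best-match identification against a local reference library.

One query per species is held out; the rest form the library. Two
species are forced onto a shared haplotype (the classic plastid-marker
failure) and one species is dropped from the library entirely, so all
three outcome classes appear: CORRECT, AMBIGUOUS_TOP (several species
tie at the top score) and BELOW_THRESHOLD (best hit under 99.5 %
identity).
"""

import plantbarcode as pb
from plantbarcode.identify import RefEntry, ReferenceLibrary, batch_classify

names = pb.SimConfig(n_species=8).species_names()
cfg = pb.SimConfig(
    n_species=8,
    n_per_species=3,
    seq_length=800,
    shared_haplotype_groups=[set(names[:2])],
    missing_reference_species={names[7]},
    seed=11,
)
seqs, truth = pb.simulate_dataset(cfg)
queries, refs, species = pb.split_query_reference(seqs, truth)

library = ReferenceLibrary([RefEntry(r, s, species[r]) for r, s in refs.records], marker="sim")
results, summary = batch_classify(queries, library, threshold=0.995, true_species=species)

for r in results:
    extra = f" tied={r.tied_species}" if len(r.tied_species) > 1 else ""
    print(
        f"{r.query_id} ({species[r.query_id]}): {r.outcome.value:16s}"
        f" identity={r.top_identity:.4f}{extra}"
    )
print(
    f"\n{summary['n_correct']} correct, {summary['n_ambiguous']} ambiguous,"
    f" {summary['n_below_threshold']} below threshold of {summary['n_queries']} queries"
)
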