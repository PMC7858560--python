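"""Best-match classifier: scoring, threshold behaviour, tie handling."""

import numpy as np
import pytest

import plantbarcode as pb
from plantbarcode.identify import (
    Outcome,
    RefEntry,
    ReferenceLibrary,
    batch_classify,
    classify_query,
    pairwise_score,
)

_COMP = {"A": "G", "C": "T", "G": "A", "T": "C"}


def mutate(seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = _COMP[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def base_seq():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), 500))


class TestPairwiseScore:
    def test_identical(self, base_seq):
        score, ident = pairwise_score(base_seq, base_seq)
        assert ident == 1.0 and score == 2.0 * len(base_seq)

    def test_single_mismatch(self, base_seq):
        _, ident = pairwise_score(mutate(base_seq, [250]), base_seq)
        assert ident == pytest.approx(499 / 500)

    def test_internal_substring_full_identity(self, base_seq):
        _, ident = pairwise_score(base_seq[100:400], base_seq)
        assert ident == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_score("", "ACGT")


class TestClassify:
    def test_exact_hit_correct(self, base_seq):
        lib = ReferenceLibrary(
            [
                RefEntry("r1", base_seq, "Aus aus"),
                RefEntry("r2", mutate(base_seq, range(0, 100, 2)), "Bus bus"),
            ]
        )
        res = classify_query(base_seq, lib)
        assert res.outcome is Outcome.CORRECT
        assert res.assigned_species == "Aus aus"
        assert res.tied_species == ["Aus aus"]

    def test_shared_haplotype_ambiguous_with_k_species(self, base_seq):
        for k in (2, 4):
            lib = ReferenceLibrary(
                [RefEntry(f"r{i}", base_seq, f"Sp {i}") for i in range(k)]
            )
            res = classify_query(base_seq, lib)
            assert res.outcome is Outcome.AMBIGUOUS_TOP
            assert len(res.tied_species) == k

    def test_divergent_best_hit_below_threshold(self, base_seq):
        lib = ReferenceLibrary([RefEntry("r1", base_seq, "Aus aus")])
        query = mutate(base_seq, range(0, 50, 5))  # 10/500 = 2% divergent
        res = classify_query(query, lib, true_species="Cus cus")
        assert res.outcome is Outcome.BELOW_THRESHOLD
        assert res.top_identity == pytest.approx(0.98)
        assert res.species_in_library is False

    def test_threshold_boundary_inclusive(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), 400))
        query = mutate(ref, [10, 210])  # 398/400 = 0.995 exactly
        lib = ReferenceLibrary([RefEntry("r", ref, "Aus aus")])
        assert classify_query(query, lib).outcome is Outcome.CORRECT
        # one more mismatch dips under the boundary
        assert (
            classify_query(mutate(ref, [10, 210, 333]), lib).outcome
            is Outcome.BELOW_THRESHOLD
        )

    def test_reference_order_invariance(self, base_seq, rng):
        entries = [
            RefEntry("r1", base_seq, "Aus aus"),
            RefEntry("r2", mutate(base_seq, [3]), "Bus bus"),
            RefEntry("r3", mutate(base_seq, [3, 7]), "Cus cus"),
        ]
        expected = classify_query(base_seq, ReferenceLibrary(list(entries)))
        for _ in range(4):
            rng.shuffle(entries)
            res = classify_query(base_seq, ReferenceLibrary(list(entries)))
            assert (res.outcome, res.assigned_species, res.tied_species) == (
                expected.outcome,
                expected.assigned_species,
                expected.tied_species,
            )

    def test_threshold_monotonicity(self, base_seq):
        lib = ReferenceLibrary([RefEntry("r1", base_seq, "Aus aus")])
        query = mutate(base_seq, [1, 2])  # identity 0.996
        lo = classify_query(query, lib, threshold=0.99)
        hi = classify_query(query, lib, threshold=0.999)
        assert lo.outcome is Outcome.CORRECT
        assert hi.outcome is Outcome.BELOW_THRESHOLD

    def test_empty_library_rejected(self, base_seq):
        with pytest.raises(ValueError):
            classify_query(base_seq, ReferenceLibrary([]))


class TestBatch:
    def test_self_identification_with_conspecific_duplicates(self):
        cfg = pb.SimConfig(n_species=5, n_per_species=3, seq_length=600, d_intra=0.0, seed=4)
        seqs, truth = pb.simulate_dataset(cfg)
        spmap = dict(zip(truth.seq_id, truth.species))
        lib = ReferenceLibrary([RefEntry(r, s, spmap[r]) for r, s in seqs.records])
        for rid, rseq in seqs.records[:5]:
            res = classify_query(rseq, lib.without(rid), query_id=rid)
            assert res.outcome is Outcome.CORRECT
            assert res.assigned_species == spmap[rid]

    def test_full_library_gap_regime_all_correct(self):
        cfg = pb.SimConfig(n_species=8, n_per_species=3, seq_length=800, seed=11)
        seqs, truth = pb.simulate_dataset(cfg)
        queries, refs, spmap = pb.split_query_reference(seqs, truth)
        lib = ReferenceLibrary([RefEntry(r, s, spmap[r]) for r, s in refs.records])
        results, summary = batch_classify(queries, lib)
        assert summary["n_correct"] == summary["n_queries"] == len(queries)

    def test_empty_query_set(self, base_seq):
        lib = ReferenceLibrary([RefEntry("r", base_seq, "Aus aus")])
        results, summary = batch_classify(pb.SeqRecordSet([]), lib)
        assert results == [] and summary["n_queries"] == 0

    def test_counts_sum(self):
        cfg = pb.SimConfig(
            n_species=6,
            n_per_species=3,
            seq_length=700,
            missing_reference_species={"Genus04 species04"},
            seed=8,
        )
        seqs, truth = pb.simulate_dataset(cfg)
        queries, refs, spmap = pb.split_query_reference(seqs, truth)
        lib = ReferenceLibrary([RefEntry(r, s, spmap[r]) for r, s in refs.records])
        results, summary = batch_classify(queries, lib, true_species=spmap)
        assert (
            summary["n_correct"] + summary["n_ambiguous"] + summary["n_below_threshold"]
            == summary["n_queries"]
        )
        missing = [r for r in results if r.query_id.startswith("S04")]
        assert missing and all(r.species_in_library is False for r in missing)
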