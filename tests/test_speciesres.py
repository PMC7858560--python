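"""Monophyly decisions and the three-way resolution outcome logic."""

import numpy as np
import pytest

import plantbarcode as pb
from plantbarcode.njtree import PhyloTree
from plantbarcode.speciesres import Level, resolution_table, resolve_sample, species_monophyletic
from conftest import random_binary_tree, steiner_monophyly


def balanced_quartet(l1="a1", l2="a2", l3="b1", l4="b2"):
    t = PhyloTree()
    u, v = t.new_internal(), t.new_internal()
    t.add_edge(u, l1, 0.1)
    t.add_edge(u, l2, 0.1)
    t.add_edge(v, l3, 0.1)
    t.add_edge(v, l4, 0.1)
    t.add_edge(u, v, 0.3)
    return t


class TestMonophyly:
    def test_cherry_is_monophyletic(self):
        t = balanced_quartet()
        assignment = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert species_monophyletic(t, assignment, "A")
        assert species_monophyletic(t, assignment, "B")

    def test_interleaved_is_not(self):
        t = balanced_quartet("a1", "b1", "a2", "b2")
        assignment = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert not species_monophyletic(t, assignment, "A")

    def test_singleton_trivially_monophyletic(self):
        t = balanced_quartet()
        assert species_monophyletic(t, {"a1": "A", "a2": "B", "b1": "B", "b2": "B"}, "A")

    def test_absent_species_is_hard_error(self):
        t = balanced_quartet()
        with pytest.raises(KeyError):
            species_monophyletic(t, {"a1": "A"}, "Z")

    def test_agrees_with_steiner_oracle_on_random_trees(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            k = int(rng.integers(1, n))
            members = frozenset(rng.choice(labels, size=k, replace=False))
            assignment = {l: ("X" if l in members else f"other_{l}") for l in labels}
            assert species_monophyletic(tree, assignment, "X") == steiner_monophyly(
                tree, members
            )

    def test_invariant_under_newick_roundtrip(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(labels, rng)
        assignment = {l: ("X" if i < 4 else "Y") for i, l in enumerate(labels)}
        back = pb.read_newick(pb.write_newick(tree))
        assert species_monophyletic(tree, assignment, "X") == species_monophyletic(
            back, assignment, "X"
        )


class TestResolveSample:
    def test_species_level(self):
        t = balanced_quartet("q", "r1", "x1", "x2")
        out = resolve_sample(
            t, {"r1": "Gymnadenia conopsea", "x1": "Orchis simia", "x2": "Orchis simia"}, None, "q"
        )
        assert out.level is Level.SPECIES
        assert out.resolved_name == "Gymnadenia conopsea"
        assert out.singleton_flag  # backed by a single reference accession

    def test_genus_fallback_when_species_intermixed(self):
        # query nested in a ladder of intermixed Dactylorhiza species: the
        # genus forms a clade around the query but no single species does
        t = PhyloTree()
        a, b, c, w = (t.new_internal() for _ in range(4))
        t.add_edge(a, "q", 0.05)
        t.add_edge(a, "m1", 0.05)
        t.add_edge(b, a, 0.05)
        t.add_edge(b, "s1", 0.05)
        t.add_edge(c, b, 0.05)
        t.add_edge(c, "m2", 0.05)
        t.add_edge(c, w, 0.5)
        t.add_edge(w, "o1", 0.1)
        t.add_edge(w, "o2", 0.1)
        out = resolve_sample(
            t,
            {
                "m1": "Dactylorhiza maculata",
                "m2": "Dactylorhiza maculata",
                "s1": "Dactylorhiza saccifera",
                "o1": "Ophrys sphegodes",
                "o2": "Ophrys sphegodes",
            },
            None,
            "q",
        )
        assert out.level is Level.GENUS_ONLY
        assert out.resolved_name == "Dactylorhiza sp."

    def test_unresolved_when_query_breaks_every_group(self):
        # two genera fully interleaved around the query: no species or genus
        # group containing the query is a split side
        t = PhyloTree()
        x, y, z = t.new_internal(), t.new_internal(), t.new_internal()
        t.add_edge(x, "a1", 0.1)
        t.add_edge(x, "b1", 0.1)
        t.add_edge(y, "a2", 0.1)
        t.add_edge(y, "b2", 0.1)
        t.add_edge(z, x, 0.1)
        t.add_edge(z, y, 0.1)
        t.add_edge(z, "q", 0.1)
        out = resolve_sample(
            t, {"a1": "Aus aus", "a2": "Aus aus", "b1": "Bus bus", "b2": "Bus bus"}, None, "q"
        )
        assert out.level is Level.UNRESOLVED
        assert out.resolved_name == ""

    def test_missing_reference_flagged(self):
        t = balanced_quartet("q", "r1", "x1", "x2")
        out = resolve_sample(
            t,
            {"r1": "Aus aus", "x1": "Bus bus", "x2": "Bus bus"},
            None,
            "q",
            expected_species="Cus cus",
        )
        assert out.missing_reference

    def test_outcome_name_shape_enforced(self):
        with pytest.raises(ValueError):
            pb.ResolutionOutcome("s", Level.SPECIES, "notabinomial")
        with pytest.raises(ValueError):
            pb.ResolutionOutcome("s", Level.GENUS_ONLY, "Genus")


class TestResolutionTable:
    def test_counts_per_marker(self):
        t_good = balanced_quartet("q1", "r1", "x1", "x2")

        # fully interleaved alternative marker: nothing resolves
        t_bad = PhyloTree()
        x, y, z = t_bad.new_internal(), t_bad.new_internal(), t_bad.new_internal()
        t_bad.add_edge(x, "r1", 0.1)
        t_bad.add_edge(x, "x1", 0.1)
        t_bad.add_edge(y, "r2", 0.1)
        t_bad.add_edge(y, "x2", 0.1)
        t_bad.add_edge(z, x, 0.1)
        t_bad.add_edge(z, y, 0.1)
        t_bad.add_edge(z, "q1", 0.1)

        refs_good = {"r1": "Aus aus", "x1": "Bus bus", "x2": "Bus bus"}
        refs_bad = {"r1": "Aus aus", "r2": "Aus aus", "x1": "Bus bus", "x2": "Bus bus"}
        long, counts = resolution_table(
            {"ITS": t_good, "accD": t_bad},
            {"ITS": refs_good, "accD": refs_bad},
            {"ITS": ["q1"], "accD": ["q1"]},
        )
        assert len(long) == 2
        c = counts.set_index("marker")["n_species_resolved"]
        assert c["ITS"] == 1 and c["accD"] == 0

    def test_empty_inputs(self):
        long, counts = resolution_table({}, {}, {})
        assert long.empty and counts.empty

    def test_perfect_gap_dataset_resolves_everything(self, rng):
        cfg = pb.SimConfig(n_species=6, n_per_species=3, seq_length=800, seed=21)
        seqs, truth = pb.simulate_dataset(cfg)
        dm = pb.distance_matrix(seqs, model="K2P")
        tree = pb.nj_build(dm)
        spmap = dict(zip(truth.seq_id, truth.species))
        for q in seqs.ids:
            refs = {l: s for l, s in spmap.items() if l != q}
            out = resolve_sample(tree, refs, None, q)
            assert out.level is Level.SPECIES
            assert out.resolved_name == spmap[q]
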