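"""Distance models: site-pattern counting, closed forms, model nesting, MCL fit."""

import math
import subprocess

import numpy as np
import pytest

import plantbarcode as pb
from plantbarcode.distmodel import (
    SubstitutionCounts,
    _TN93Spectral,
    count_site_patterns,
    jc_distance,
    k2p_distance,
    p_distance,
    tn93_distance,
    tn93_rate_matrix,
)
from plantbarcode.synthetic import _evolve, _BASES


def counts_from(n, ident, ts_pur, ts_pyr, tv, freqs=(0.25, 0.25, 0.25, 0.25)):
    return SubstitutionCounts(n, ident, ts_pur, ts_pyr, tv, np.asarray(freqs, float))


class TestSitePatterns:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("ACGT", "ACGA", dict(n_sites=4, identical=3, ts_purine=0, transversions=1)),
            ("AC-T", "ACGT", dict(n_sites=3, identical=3)),
            ("ACGT", "GCGT", dict(ts_purine=1, identical=3)),
            ("ACGT", "ATGT", dict(ts_pyrimidine=1, identical=3)),
            ("ACGN", "ACGT", dict(n_sites=3, identical=3)),
        ],
    )
    def test_examples(self, a, b, expect):
        c = count_site_patterns(a, b)
        for k, v in expect.items():
            assert getattr(c, k) == v, k

    def test_no_comparable_sites_is_undefined_signal(self):
        c = count_site_patterns("----", "ACGT")
        assert c.n_sites == 0
        assert pb.is_undefined(p_distance(c))

    def test_counts_partition_sites_and_freqs_sum(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGTN-"), 60))
            b = "".join(rng.choice(list("ACGTN-"), 60))
            c = count_site_patterns(a, b)
            if c.n_sites:
                assert c.identical + c.transitions + c.transversions == c.n_sites
                assert abs(c.freqs.sum() - 1.0) < 1e-9

    def test_complete_vs_pairwise_on_gapfree(self, rng):
        seqs = pb.SeqRecordSet(
            [(f"s{i}", "".join(rng.choice(list("ACGT"), 300))) for i in range(5)]
        )
        d1 = pb.distance_matrix(seqs, model="K2P", deletion="pairwise")
        d2 = pb.distance_matrix(seqs, model="K2P", deletion="complete")
        np.testing.assert_allclose(d1.values, d2.values)


class TestClosedForms:
    def test_p_distance_examples(self):
        assert p_distance(counts_from(4, 3, 0, 0, 1)) == 0.25
        assert p_distance(counts_from(4, 4, 0, 0, 0)) == 0.0
        assert p_distance(counts_from(4, 0, 0, 0, 4)) == 1.0

    def test_jc_closed_form(self):
        assert jc_distance(counts_from(100, 100, 0, 0, 0)) == 0.0
        # p = 0.25: d = -(3/4) ln(1 - 1/3), evaluated independently
        assert jc_distance(counts_from(100, 75, 10, 10, 5)) == pytest.approx(
            -0.75 * math.log(1 - 1 / 3), rel=1e-12
        )
        assert pb.is_undefined(jc_distance(counts_from(100, 25, 25, 25, 25)))

    def test_identical_sequences_zero_under_all_models(self):
        c = count_site_patterns("ACGTACGT", "ACGTACGT")
        for fn in (p_distance, jc_distance, k2p_distance, tn93_distance):
            assert fn(c) == 0.0

    def test_tn93_reduces_to_k2p_at_equal_freqs_and_pooled_transitions(self):
        c = counts_from(1000, 900, 30, 30, 40)
        assert tn93_distance(c) == pytest.approx(k2p_distance(c), rel=1e-12)

    def test_k2p_reduces_to_jc_at_transition_fraction_half(self):
        # transitions:transversions = 1:2 means no transition bias (kappa = 0.5)
        c = counts_from(3000, 2700, 50, 50, 200)
        assert k2p_distance(c) == pytest.approx(jc_distance(c), rel=1e-12)

    def test_monotone_in_p_at_fixed_composition(self):
        # scale up differences proportionally; all models must not decrease
        last = {fn: -1.0 for fn in (p_distance, jc_distance, k2p_distance, tn93_distance)}
        for k in range(1, 8):
            c = counts_from(1000, 1000 - 7 * k, 3 * k, 2 * k, 2 * k)
            for fn in last:
                d = fn(c)
                assert d > last[fn]
                last[fn] = d

    def test_saturation_yields_undefined_not_nan_silently(self):
        c = counts_from(100, 10, 40, 40, 10)
        assert pb.is_undefined(tn93_distance(c))
        assert pb.is_undefined(k2p_distance(counts_from(100, 20, 40, 0, 40)))


class TestAgainstApe:
    """Cross-check the per-pair closed forms against R's ape::dist.dna."""

    def test_distance_models_match_ape(self, tmp_path, rng):
        cfg = pb.SimConfig(
            n_species=5, n_per_species=1, seq_length=1500, d_inter=0.12, d_intra=0, seed=7
        )
        seqs, _ = pb.simulate_dataset(cfg)
        pb.write_fasta(seqs, tmp_path / "a.fa")
        script = (
            f'library(ape); s <- read.dna("{tmp_path}/a.fa", format="fasta"); '
            'for (m in c("raw","JC69","K80","TN93")) '
            'cat(m, format(as.vector(dist.dna(s, model=m, pairwise.deletion=TRUE)), digits=12), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = {}
        for line in out.stdout.strip().splitlines():
            parts = line.split()
            ref[parts[0]] = np.array([float(x) for x in parts[1:]])
        # ape pools base frequencies over the whole alignment for TN93
        codes = np.stack([np.frombuffer(s.encode(), np.uint8) for s in seqs.sequences])
        pooled = np.array(
            [(codes == ord(b)).mean() for b in "ACGT"]
        )
        n = len(seqs)
        for model, rname in (("p", "raw"), ("JC", "JC69"), ("K2P", "K80")):
            dm = pb.distance_matrix(seqs, model=model)
            mine = dm.values[np.triu_indices(n, 1)]
            np.testing.assert_allclose(mine, ref[rname], atol=1e-10)
        tn = np.array(
            [
                tn93_distance(
                    count_site_patterns(seqs.sequences[i], seqs.sequences[j]), freqs=pooled
                )
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )
        np.testing.assert_allclose(tn, ref["TN93"], atol=1e-10)


class TestTN93Machinery:
    def test_rate_matrix_is_proper_and_unit_rate(self):
        pi = np.array([0.26, 0.24, 0.23, 0.27])
        Q = tn93_rate_matrix(pi, 4.0, 2.0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)
        np.testing.assert_allclose(pi @ Q, 0.0, atol=1e-12)  # stationarity

    def test_spectral_matches_expm(self):
        from scipy.linalg import expm

        spec = _TN93Spectral((0.3, 0.2, 0.3, 0.2), 5.0, 1.5)
        for t in (0.01, 0.2, 2.0):
            np.testing.assert_allclose(
                spec.transition_matrix(t),
                expm(tn93_rate_matrix(spec.pi, 5.0, 1.5) * t),
                atol=1e-10,
            )

    def test_tn93_estimator_unbiased_on_simulated_pairs(self, rng):
        spec = _TN93Spectral((0.26, 0.24, 0.23, 0.27), 4.0, 2.0)
        L, reps, d_true = 1000, 40, 0.1
        P = spec.transition_matrix(d_true)
        est = []
        for _ in range(reps):
            a = rng.choice(4, size=L, p=spec.pi).astype(np.int8)
            b = _evolve(a, P, rng)
            c = count_site_patterns("".join(_BASES[a]), "".join(_BASES[b]))
            est.append(tn93_distance(c))
        est = np.array(est)
        sem = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - d_true) < 3 * sem


class TestMCL:
    def test_two_identical_sequences(self):
        seqs = pb.SeqRecordSet([("a", "ACGT" * 100), ("b", "ACGT" * 100)])
        dm = pb.mcl_distance_matrix(seqs)
        assert dm.values[0, 1] == 0.0

    def test_matches_jc_on_jc_data(self, rng):
        # equal frequencies, no transition bias: MCL must collapse to JC
        spec = _TN93Spectral((0.25,) * 4, 1.0, 1.0)
        L = 10_000
        root = rng.choice(4, size=L).astype(np.int8)
        seqs = [("r", root)]
        for i, d in enumerate((0.05, 0.1, 0.2)):
            seqs.append((f"s{i}", _evolve(root, spec.transition_matrix(d), rng)))
        recs = pb.SeqRecordSet([(n, "".join(_BASES[s])) for n, s in seqs])
        mcl = pb.mcl_distance_matrix(recs)
        jc = pb.distance_matrix(recs, model="JC")
        iu = np.triu_indices(len(recs), 1)
        np.testing.assert_allclose(mcl.values[iu], jc.values[iu], rtol=0.02)

    def test_recovers_generating_kappas(self, rng):
        spec = _TN93Spectral((0.26, 0.24, 0.23, 0.27), 4.0, 2.0)
        L = 10_000
        root = rng.choice(4, size=L, p=spec.pi).astype(np.int8)
        names_seqs = [("r", root)]
        for i, d in enumerate((0.05, 0.1, 0.15, 0.2)):
            names_seqs.append((f"s{i}", _evolve(root, spec.transition_matrix(d), rng)))
        recs = pb.SeqRecordSet([(n, "".join(_BASES[s])) for n, s in names_seqs])
        dm = pb.mcl_distance_matrix(recs)
        assert dm.params["kappa1"] == pytest.approx(4.0, rel=0.10)
        assert dm.params["kappa2"] == pytest.approx(2.0, rel=0.10)

    def test_undefined_pair_raises_in_matrix(self):
        seqs = pb.SeqRecordSet([("a", "ACGT"), ("b", "----"), ("c", "ACGT")])
        with pytest.raises(ValueError, match="comparable"):
            pb.mcl_distance_matrix(seqs)

    def test_symmetry_zero_diagonal_and_export(self, tmp_path, rng):
        cfg = pb.SimConfig(n_species=4, n_per_species=2, seq_length=400, seed=3)
        seqs, _ = pb.simulate_dataset(cfg)
        dm = pb.mcl_distance_matrix(seqs)
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values[np.isfinite(dm.values)] >= 0)
        dm.to_tsv(tmp_path / "d.tsv")
        dm.to_phylip(tmp_path / "d.phy")
        assert (tmp_path / "d.phy").read_text().splitlines()[0].strip() == str(dm.n)

    def test_saturation_cap_replaces_undefined(self):
        dm = pb.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]]),
            "TN93",
        )
        capped = dm.capped(5.0)
        assert capped.values[0, 2] == 5.0
        assert capped.n_undefined_pairs == 0
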