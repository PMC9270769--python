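import numpy as np
import pytest
from scipy import stats

import tumorspace as ts
from tumorspace.mol_evo import (
    BASES,
    CHANNEL_LABELS,
    _CTX_OF_CHANNEL,
    Genome,
    SubstitutionModel,
    _ctx_ids,
    context_counts,
    evolve_branch,
    replay_records,
    total_rate,
)


class TestAncestralGenome:
    def test_degenerate_frequencies(self):
        g = ts.generate_ancestral_genome(10, (1, 0, 0, 0), seed=0)
        assert str(g) == "AAAAAAAAAA"

    def test_composition_converges(self):
        g = ts.generate_ancestral_genome(10000, (0.3, 0.2, 0.2, 0.3), seed=1)
        sd = np.sqrt(0.3 * 0.7 / 10000)
        assert abs(g.composition()[0] - 0.3) < 3 * sd

    def test_deterministic_given_seed(self):
        a = ts.generate_ancestral_genome(500, (0.25,) * 4, seed=7)
        b = ts.generate_ancestral_genome(500, (0.25,) * 4, seed=7)
        assert str(a) == str(b)

    @pytest.mark.parametrize("nu", [(-0.1, 0.4, 0.4, 0.3), (0.3, 0.3, 0.3, 0.3)])
    def test_invalid_frequencies_rejected(self, nu):
        with pytest.raises(ValueError):
            ts.generate_ancestral_genome(10, nu)


class TestISA:
    def test_zero_length_branch_has_no_mutations(self):
        tree = ts.parse_newick("(A:0,B:2):0;")
        g = ts.generate_ancestral_genome(100, (0.25,) * 4, seed=0)
        counts, _ = ts.simulate_isa(tree, g, 0.01, seed=1)
        by_name = {n.name: c for n, c in counts.items() if n.name}
        assert by_name["A"] == 0

    def test_mutation_count_is_poisson(self):
        """Exponential-accumulation counts on one branch follow
        Poisson(L * mu * t)."""
        tree = ts.parse_newick("(A:2);")
        g = ts.generate_ancestral_genome(500, (0.25,) * 4, seed=0)
        rng = np.random.default_rng(3)
        lam = 500 * 1e-3 * 2
        counts = []
        for _ in range(2000):
            _, recs = ts.simulate_isa(tree, g, 1e-3, rng=rng)
            counts.append(len(recs["A"]))
        counts = np.asarray(counts)
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / len(counts))

    def test_sites_unique_and_union_along_paths(self):
        tree = ts.parse_newick("((A:1,B:1):1,C:2):0;")
        g = ts.generate_ancestral_genome(2000, (0.25,) * 4, seed=0)
        _, recs = ts.simulate_isa(tree, g, 5e-3, seed=5)
        site_of = {}
        for rs in recs.values():
            for r in rs:
                site_of.setdefault(id(r), r.position)
        assert len(set(site_of.values())) == len(site_of)  # ISA uniqueness
        shared = {r.position for r in recs["A"]} & {r.position for r in recs["B"]}
        stem = {r.position for r in recs["A"] if r in recs["B"]}
        assert shared == stem  # exactly the root->parent path

    def test_saturation_raises(self):
        tree = ts.parse_newick("(A:1000);")
        g = ts.generate_ancestral_genome(5, (0.25,) * 4, seed=0)
        with pytest.raises(RuntimeError, match="saturation"):
            ts.simulate_isa(tree, g, 1.0, seed=1)


class TestRateMatrices:
    def test_jc69_symmetric_off_diagonals(self):
        Q = ts.build_rate_matrix("JC69", rate=0.8).Q
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.2)

    def test_rows_sum_to_zero(self):
        for name, kw in [("JC69", {}), ("K80", {"kappa": 3}),
                         ("F81", {"freqs": (0.3, 0.2, 0.2, 0.3)}),
                         ("HKY85", {"kappa": 2, "freqs": (0.3, 0.2, 0.2, 0.3)}),
                         ("TN93", {"kappa_AG": 2, "kappa_CT": 3,
                                   "freqs": (0.3, 0.2, 0.2, 0.3)}),
                         ("K81", {"kappa1": 2, "kappa2": 3})]:
            Q = ts.build_rate_matrix(name, rate=1.0, **kw).Q
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_hky_with_unit_kappa_is_f81(self):
        freqs = (0.3, 0.2, 0.2, 0.3)
        hky = ts.build_rate_matrix("HKY85", rate=0.5, kappa=1.0, freqs=freqs)
        f81 = ts.build_rate_matrix("F81", rate=0.5, freqs=freqs)
        assert np.allclose(hky.Q, f81.Q, atol=1e-12)

    def test_tn93_with_equal_transitions_is_hky(self):
        freqs = (0.1, 0.4, 0.2, 0.3)
        tn = ts.build_rate_matrix("TN93", rate=1.0, kappa_AG=2.5, kappa_CT=2.5,
                                  freqs=freqs)
        hky = ts.build_rate_matrix("HKY85", rate=1.0, kappa=2.5, freqs=freqs)
        assert np.allclose(tn.Q, hky.Q, atol=1e-12)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown substitution model"):
            ts.build_rate_matrix("GTR")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ts.build_rate_matrix("JC69", rate=0.0)


class TestEvolveBranch:
    def test_zero_rates_leave_sequence_unchanged(self):
        model = SubstitutionModel(name="null", Q=np.zeros((4, 4)))
        g = ts.generate_ancestral_genome(200, (0.25,) * 4, seed=0)
        out, recs, _ = evolve_branch(g.seq, model, None, 10.0,
                                     np.random.default_rng(0))
        assert recs == [] and np.array_equal(out, g.seq)

    def test_jc69_divergence_matches_closed_form(self):
        """Fraction of differing sites after time t equals
        3/4 (1 - exp(-4 mu' t / 3)) for per-site rate mu'."""
        L, rate, t = 2000, 1.0, 0.2
        model = ts.build_rate_matrix("JC69", rate=rate)
        mu_prime = 3 * rate / 4
        expected = 0.75 * (1 - np.exp(-4 * mu_prime * t / 3))
        rng = np.random.default_rng(8)
        g = ts.generate_ancestral_genome(L, (0.25,) * 4, rng=rng)
        diffs = []
        for _ in range(100):
            out, _, _ = evolve_branch(g.seq, model, None, t, rng)
            diffs.append(np.mean(out != g.seq))
        se = np.sqrt(expected * (1 - expected) / L / len(diffs))
        assert abs(np.mean(diffs) - expected) < 3 * se

    def test_indel_count_linearises_for_short_branches(self):
        model = SubstitutionModel(name="null", Q=np.zeros((4, 4)))
        indels = ts.IndelModel(mu_indel=1e-4, L_indel=5, a=2.0)
        rng = np.random.default_rng(9)
        g = ts.generate_ancestral_genome(1000, (0.25,) * 4, rng=rng)
        t = 0.5
        lam = 1000 * 1e-4 * t
        n = [len(evolve_branch(g.seq, model, indels, t, rng)[1])
             for _ in range(2000)]
        assert abs(np.mean(n) - lam) < 3 * np.sqrt(lam / len(n))

    def test_replay_reproduces_child_sequence(self):
        """Heritability: a child's sequence differs from its parent exactly
        by the branch's mutation records."""
        model = ts.build_rate_matrix("HKY85", rate=2e-3, kappa=2.0,
                                     freqs=(0.3, 0.2, 0.2, 0.3))
        indels = ts.IndelModel(mu_indel=2e-4, L_indel=8, a=1.5)
        rng = np.random.default_rng(10)
        g = ts.generate_ancestral_genome(800, (0.25,) * 4, rng=rng)
        out, recs, _ = evolve_branch(g.seq, model, indels, 5.0, rng)
        assert len(recs) > 5
        assert np.array_equal(replay_records(g.seq, recs), out)

    def test_incremental_rate_matches_recomputation(self):
        """Total-rate bookkeeping under interleaved SNVs and indels."""
        model = ts.build_rate_matrix("TN93", rate=5e-3, kappa_AG=2, kappa_CT=3,
                                     freqs=(0.3, 0.2, 0.2, 0.3))
        indels = ts.IndelModel(mu_indel=5e-4, L_indel=6, a=2.0)
        rng = np.random.default_rng(11)
        g = ts.generate_ancestral_genome(400, (0.25,) * 4, rng=rng)
        evolve_branch(g.seq, model, indels, 4.0, rng, validate=True)

    def test_long_branch_allows_multiple_hits(self):
        model = ts.build_rate_matrix("JC69", rate=1.0)
        rng = np.random.default_rng(12)
        g = ts.generate_ancestral_genome(100, (0.25,) * 4, rng=rng)
        _, recs, _ = evolve_branch(g.seq, model, None, 5.0, rng)
        sites = [r.position for r in recs]
        assert len(sites) > len(set(sites))  # some site hit at least twice


class TestLavalette:
    def test_single_length(self):
        rng = np.random.default_rng(0)
        assert all(ts.sample_indel_length(1, 2.0, rng) == 1 for _ in range(10))

    def test_empirical_matches_enumerated_weights(self):
        rng = np.random.default_rng(1)
        probs = ts.lavalette_weights(10, 2.0)
        draws = rng.choice(np.arange(1, 11), p=probs, size=20000)
        draws2 = np.array([ts.sample_indel_length(10, 2.0, rng)
                           for _ in range(20000)])
        obs = np.bincount(draws2, minlength=11)[1:]
        chi2, p = stats.chisquare(obs, probs * len(draws2))
        assert p > 0.01

    def test_large_exponent_concentrates_on_one(self):
        w = ts.lavalette_weights(10, 8.0)
        assert w[0] > 0.99
        assert (np.diff(ts.lavalette_weights(10, 2.0)) < 0).all()


class TestIndependentIndels:
    def test_zero_rate_is_noop(self):
        tree = ts.parse_newick("((A:1,B:1):1);")
        g = ts.generate_ancestral_genome(300, (0.25,) * 4, seed=0)
        model = ts.build_rate_matrix("JC69", rate=1e-3)
        indels = ts.IndelModel(mu_indel=0.0, L_indel=5, a=2.0)
        seqs, _ = ts.evolve_tree(tree, g, model, indels=indels,
                                 mode="independent", seed=1)
        assert all(len(s.seq) == 300 for s in seqs.values())

    def test_mean_count_matches_poisson(self):
        tree = ts.parse_newick("(A:2);")
        g = ts.generate_ancestral_genome(500, (0.25,) * 4, seed=0)
        model = SubstitutionModel(name="null", Q=np.zeros((4, 4)))
        indels = ts.IndelModel(mu_indel=2e-4, L_indel=5, a=2.0)
        rng = np.random.default_rng(2)
        lam = 500 * 2e-4 * 2
        n = []
        for _ in range(2000):
            _, recs = ts.evolve_tree(tree, g, model, indels=indels,
                                     mode="independent", rng=rng)
            n.append(len(recs["A"]))
        assert abs(np.mean(n) - lam) < 3 * np.sqrt(lam / len(n))

    def test_modes_agree_in_expectation_at_small_rates(self):
        tree = ts.parse_newick("(A:1);")
        g = ts.generate_ancestral_genome(400, (0.25,) * 4, seed=0)
        model = SubstitutionModel(name="null", Q=np.zeros((4, 4)))
        indels = ts.IndelModel(mu_indel=1e-4, L_indel=5, a=2.0)
        rng = np.random.default_rng(3)
        joint, indep = [], []
        for _ in range(1500):
            _, r1 = ts.evolve_tree(tree, g, model, indels=indels, mode="joint",
                                   rng=rng)
            _, r2 = ts.evolve_tree(tree, g, model, indels=indels,
                                   mode="independent", rng=rng)
            joint.append(len(r1["A"]))
            indep.append(len(r2["A"]))
        lam = 400 * 1e-4
        se = np.sqrt(2 * lam / 1500)
        assert abs(np.mean(joint) - np.mean(indep)) < 3 * se


class TestSignatures:
    def one_channel_model(self, channels, activities=None, change_times=(),
                          xi=1.0, mu_avg=1e-3):
        sigs = {}
        for i, c in enumerate(channels):
            v = np.zeros(96)
            v[c] = 1.0
            sigs[f"S{i}"] = v
        return ts.SignatureModel(signatures=sigs, mu_avg=mu_avg, xi=xi,
                                 change_times=change_times,
                                 activities=activities)

    def test_context_counts_match_manual_enumeration(self):
        g = Genome.from_string("ACGTACGTTTA")
        counts = context_counts(g.seq)
        # manual: interior positions 1..9 folded onto the pyrimidine strand
        manual = np.zeros(32, dtype=int)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        s = str(g)
        for k in range(1, len(s) - 1):
            tri = s[k - 1: k + 2]
            if tri[1] in "AG":
                tri = "".join(comp[b] for b in reversed(tri))
            pyr = 0 if tri[1] == "C" else 1
            idx = pyr * 16 + "ACGT".index(tri[0]) * 4 + "ACGT".index(tri[2])
            manual[idx] += 1
        assert np.array_equal(counts, manual)

    def test_xi_zero_gives_uniform_background_rates(self):
        model = self.one_channel_model([0], xi=0.0, mu_avg=2e-3)
        counts = np.arange(32)
        rates = ts.build_signature_rates(counts, model, t=0.0)
        assert np.allclose(rates, 2e-3 * counts[_CTX_OF_CHANNEL] / 96)

    def test_xi_one_single_channel_only_that_class(self):
        channel = CHANNEL_LABELS.index("A[C>T]A")
        model = self.one_channel_model([channel], xi=1.0, mu_avg=5e-3)
        g = ts.generate_ancestral_genome(3000, (0.25,) * 4, seed=4)
        _, recs = ts.evolve_branch_signatures(g.seq, model, 0.0, 60.0,
                                              np.random.default_rng(5))
        assert len(recs) > 10
        for r in recs:
            assert (r.ref, r.alt) in {("C", "T"), ("G", "A")}

    def test_two_signature_mixture_is_arithmetic_mean(self):
        m1 = self.one_channel_model([3])
        m2 = self.one_channel_model([40])
        mix = ts.SignatureModel(
            signatures={"A": m1.P[0], "B": m2.P[0]}, mu_avg=1e-3, xi=1.0,
            activities=[[0.5, 0.5]])
        counts = np.ones(32)
        r_mix = ts.build_signature_rates(counts, mix, 0.0)
        r1 = ts.build_signature_rates(counts, m1, 0.0)
        r2 = ts.build_signature_rates(counts, m2, 0.0)
        assert np.allclose(r_mix, (r1 + r2) / 2)

    def test_change_point_splits_spectrum(self):
        c_early = CHANNEL_LABELS.index("A[C>A]A")
        c_late = CHANNEL_LABELS.index("T[T>G]T")
        model = self.one_channel_model(
            [c_early, c_late], change_times=(100.0,),
            activities=[[1.0, 0.0], [0.0, 1.0]], mu_avg=2e-3)
        g = ts.generate_ancestral_genome(5000, (0.25,) * 4, seed=6)
        _, recs = ts.evolve_branch_signatures(g.seq, model, 0.0, 200.0,
                                              np.random.default_rng(7))
        early = [r for r in recs if r.time < 100.0]
        late = [r for r in recs if r.time >= 100.0]
        assert early and late
        assert all((r.ref, r.alt) in {("C", "A"), ("G", "T")} for r in early)
        assert all((r.ref, r.alt) in {("T", "G"), ("A", "C")} for r in late)

    def test_activities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            self.one_channel_model([0, 1], activities=[[0.7, 0.2]])

    def test_negative_branch_interval_rejected(self):
        model = self.one_channel_model([0])
        g = ts.generate_ancestral_genome(100, (0.25,) * 4, seed=0)
        with pytest.raises(ValueError, match="timeline"):
            ts.evolve_branch_signatures(g.seq, model, -1.0, 2.0,
                                        np.random.default_rng(0))

    def test_terminal_bases_never_mutate(self):
        channel = CHANNEL_LABELS.index("A[C>T]A")
        model = self.one_channel_model([channel], mu_avg=5e-3)
        g = ts.generate_ancestral_genome(1000, (0.25,) * 4, seed=8)
        _, recs = ts.evolve_branch_signatures(g.seq, model, 0.0, 50.0,
                                              np.random.default_rng(9))
        assert all(1 < r.position < len(g.seq) for r in recs)


class TestIO:
    def test_signature_fixture_round_trip(self, tmp_path):
        path = ts.generate_fixtures("signature_table", tmp_path, n_signatures=3)
        table = ts.read_signature_table(path)
        assert len(table) == 3
        for v in table.values():
            assert v.shape == (96,)
            assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_one_channel_fixture(self, tmp_path):
        path = ts.generate_fixtures("signature_table", tmp_path,
                                    n_signatures=2, one_channel=True)
        for v in ts.read_signature_table(path).values():
            assert (v == 1.0).sum() == 1 and v.sum() == 1.0

    def test_fasta_and_mutation_table_writers(self, tmp_path):
        seqs = {"X": Genome.from_string("ACGT" * 10)}
        recs = {"X": [ts.MutationRecord(kind="SNV", position=3, ref="G",
                                        alt="T", time=1.0, anc_position=3)]}
        paths = ts.write_sample_fasta(seqs, tmp_path / "fa")
        from Bio import SeqIO
        rec = next(SeqIO.parse(paths[0], "fasta"))
        assert str(rec.seq) == "ACGT" * 10
        ts.write_mutation_table(recs, tmp_path / "mut.tsv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "mut.tsv", sep="\t")
        assert df.iloc[0]["type"] == "SNV" and df.iloc[0]["position"] == 3
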