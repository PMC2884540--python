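"""Benchmark pipelines: distance trees, bootstrap, sampling, statistics."""

import networkx as nx
import numpy as np
import pytest

from phylobench import (
    Alignment,
    DistanceTreeBuilder,
    EmulatorAligner,
    EvaluationRecord,
    OrthologTable,
    ReferenceTopology,
    SampleFailure,
    SimulationConfig,
    bootstrap_support,
    build_homolog_families,
    builtin_distance_tree,
    comb_tree,
    compare_methods,
    nontrivial_splits,
    parse_newick,
    relabel_leaves,
    robinson_foulds,
    run_discordance_test,
    run_minimum_duplication_test,
    sample_ortholog_set,
    simulate_orthologs,
    summarize_records,
    tree_accuracy,
)
from conftest import make_alignment


def quartet_alignment():
    """Four sequences whose p-distances are additive on ((A,B),(C,D))."""
    base = "A" * 100
    a = base
    b = base[:98] + "CC"  # A-B differ at 2 sites
    c = "C" * 30 + base[30:]  # far clade
    d = "C" * 30 + base[30:68] + "GG" + base[70:]
    return Alignment(ids=["A", "B", "C", "D"], rows=[a, b, c, d], alphabet="aa")


class TestDistanceTree:
    def test_recovers_additive_quartet(self):
        tree = builtin_distance_tree(quartet_alignment())
        expected = parse_newick("((A,B),(C,D));")
        assert robinson_foulds(tree, expected) == 0

    def test_identical_sequences_deterministic(self):
        aln = make_alignment("ACDEF", "ACDEF", "ACDEF", ids=["a", "b", "c"])
        t1 = builtin_distance_tree(aln)
        t2 = builtin_distance_tree(aln)
        from phylobench import write_newick

        assert write_newick(t1) == write_newick(t2)
        assert t1.leaf_labels == {"a", "b", "c"}

    def test_input_order_invariance(self):
        aln = quartet_alignment()
        reordered = Alignment(
            ids=list(reversed(aln.ids)),
            rows=list(reversed(aln.rows)),
            alphabet="aa",
        )
        assert robinson_foulds(
            builtin_distance_tree(aln), builtin_distance_tree(reordered)
        ) == 0

    def test_no_shared_sites_capped_not_crashing(self):
        aln = make_alignment("AC--", "--DE", "ACDE", ids=["a", "b", "c"])
        tree = builtin_distance_tree(aln)
        assert tree.leaf_labels == {"a", "b", "c"}


class TestBootstrap:
    def test_uniform_columns_full_support(self):
        aln = quartet_alignment()
        support = bootstrap_support(aln, DistanceTreeBuilder(), 20, rng_seed=1)
        assert support == 1.0

    def test_same_seed_same_support(self, small_simulated_family):
        aln = small_simulated_family.true_alignment
        builder = DistanceTreeBuilder()
        s1 = bootstrap_support(aln, builder, 25, rng_seed=7)
        s2 = bootstrap_support(aln, builder, 25, rng_seed=7)
        assert s1 == s2

    def test_matches_independent_resampling_oracle(self, small_simulated_family):
        aln = small_simulated_family.true_alignment
        builder = DistanceTreeBuilder()
        seed, reps = 13, 30
        ours = bootstrap_support(aln, builder, reps, rng_seed=seed)
        # oracle: same resampling scheme, independently written comparison
        rng = np.random.default_rng(seed)
        base = nontrivial_splits(builder.build(aln))
        agree = 0
        for _ in range(reps):
            cols = rng.integers(aln.width, size=aln.width)
            rows = ["".join(r[j] for j in cols) for r in aln.rows]
            rep = Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)
            if nontrivial_splits(builder.build(rep)) == base:
                agree += 1
        assert ours == pytest.approx(agree / reps)


class TestOrthologSampling:
    def make_reference(self):
        tree = comb_tree(["cladeA", "cladeB", "cladeC"])
        candidates = {
            "cladeA": ["sp1", "sp2"],
            "cladeB": ["sp3"],
            "cladeC": ["sp4"],
        }
        return ReferenceTopology(tree=tree, candidates=candidates)

    def make_table(self):
        return OrthologTable(
            species_sequences={
                "sp1": ["sp1_g1"],
                "sp2": ["sp2_g1", "sp2_g2"],
                "sp3": ["sp3_g1"],
                "sp4": ["sp4_g1", "sp4_g2"],
            },
            orthologs={
                frozenset(p)
                for p in [
                    ("sp1_g1", "sp3_g1"),
                    ("sp1_g1", "sp4_g1"),
                    ("sp2_g1", "sp3_g1"),
                    ("sp2_g1", "sp4_g2"),
                    ("sp2_g2", "sp3_g1"),
                    ("sp2_g2", "sp4_g1"),
                ]
            },
        )

    def test_innermost_leaf_is_deepest(self):
        assert self.make_reference().innermost_leaf() == "cladeA"

    def test_unique_candidates_forced_choice(self):
        ref = ReferenceTopology(
            tree=comb_tree(["cladeA", "cladeB", "cladeC"]),
            candidates={"cladeA": ["sp1"], "cladeB": ["sp3"], "cladeC": ["sp4"]},
        )
        table = self.make_table()
        for seed in (0, 1, 99):
            fam = sample_ortholog_set(ref, table, rng_seed=seed)
            assert sorted(fam.genes) == ["sp1_g1", "sp3_g1", "sp4_g1"]

    def test_same_seed_identical_sample(self):
        ref, table = self.make_reference(), self.make_table()
        a = sample_ortholog_set(ref, table, rng_seed=5)
        b = sample_ortholog_set(ref, table, rng_seed=5)
        assert a.genes == b.genes and a.species == b.species

    def test_sampled_set_is_mutually_orthologous_to_start(self):
        ref, table = self.make_reference(), self.make_table()
        fam = sample_ortholog_set(ref, table, rng_seed=3)
        assert len(fam.genes) == 3
        assert len(set(fam.species.values())) == 3

    def test_no_candidates_fails_sample(self):
        ref = ReferenceTopology(
            tree=comb_tree(["cladeA", "cladeB", "cladeC"]),
            candidates={"cladeA": ["sp1"], "cladeB": ["sp9"], "cladeC": ["sp4"]},
        )
        with pytest.raises(SampleFailure):
            sample_ortholog_set(ref, self.make_table(), rng_seed=0)


class TestHomologFamilies:
    def test_threshold_and_components(self):
        g = nx.Graph()
        g.add_edge("A", "B", evalue=1e-12)
        g.add_edge("B", "C", evalue=1e-11)
        g.add_edge("C", "D", evalue=1e-5)
        species = {x: f"sp_{x}" for x in "ABCD"}
        fams = build_homolog_families(g, species)
        assert len(fams) == 1
        assert fams[0].genes == ["A", "B", "C"]

    def test_cap_downsamples(self):
        g = nx.Graph()
        members = [f"g{i:02d}" for i in range(70)]
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b, evalue=1e-20)
        species = {m: f"sp{i}" for i, m in enumerate(members)}
        fams = build_homolog_families(g, species, cap=60, rng_seed=4)
        assert len(fams) == 1
        assert len(fams[0].genes) == 60
        assert set(fams[0].genes) <= set(members)

    def test_empty_graph(self):
        assert build_homolog_families(nx.Graph(), {}) == []


class TestPipelines:
    def test_closed_loop_perfect_accuracy(self, six_taxon_reference):
        samples = [
            simulate_orthologs(SimulationConfig(seed=100 + i, indel_rate=0.0))
            for i in range(3)
        ]
        recs = run_discordance_test(
            samples,
            six_taxon_reference,
            [EmulatorAligner("true", 0.0)],
            DistanceTreeBuilder(),
            base_seed=0,
        )
        assert all(r.score == 1.0 for r in recs)

    def test_identical_methods_identical_records(self, six_taxon_reference):
        samples = [simulate_orthologs(SimulationConfig(seed=200 + i)) for i in range(3)]
        recs = run_discordance_test(
            samples,
            six_taxon_reference,
            [EmulatorAligner("m1", 0.0), EmulatorAligner("m2", 0.0)],
            DistanceTreeBuilder(),
            base_seed=0,
        )
        by_method = {}
        for r in recs:
            by_method.setdefault(r.method_id, []).append(r.score)
        assert by_method["m1"] == by_method["m2"]

    def test_mindup_single_copy_families_score_zero(self):
        from phylobench import simulate_family_with_duplications

        samples = [
            simulate_family_with_duplications(
                SimulationConfig(seed=300 + i, duplications=0)
            )
            for i in range(3)
        ]
        recs = run_minimum_duplication_test(
            samples, [EmulatorAligner("true", 0.0)], DistanceTreeBuilder(), base_seed=0
        )
        assert all(r.score == 0.0 for r in recs)

    def test_failures_become_exclusions_not_crashes(self, six_taxon_reference):
        class FailingAligner:
            method_id = "broken"

            def align(self, sample, guide_tree=None, seed=0):
                raise SampleFailure("boom")

        samples = [simulate_orthologs(SimulationConfig(seed=400))]
        recs = run_discordance_test(
            samples,
            six_taxon_reference,
            [FailingAligner()],
            DistanceTreeBuilder(),
        )
        assert len(recs) == 1 and recs[0].excluded and "boom" in recs[0].reason

    def test_contamination_does_not_flip_ranking(self, six_taxon_reference):
        # swapping two species' sequences in a fifth of the samples — the
        # same perturbation seen by every method — must not reverse the
        # better-vs-worse emulator ordering
        samples = []
        for i in range(25):
            fam = simulate_orthologs(SimulationConfig(seed=500 + i))
            if i % 5 == 0:
                rows = fam.true_alignment.rows
                i1, i2 = 0, 3
                rows[i1], rows[i2] = rows[i2], rows[i1]
                seqs = fam.true_alignment.ungapped()
                fam.sequences.update(seqs)
            samples.append(fam)
        aligners = [EmulatorAligner("good", 0.0), EmulatorAligner("bad", 0.6)]
        recs = run_discordance_test(
            samples, six_taxon_reference, aligners, DistanceTreeBuilder(), base_seed=1
        )
        summary = summarize_records(recs).set_index("method")
        assert summary.loc["good", "mean"] > summary.loc["bad", "mean"]


class TestSummaryAndComparison:
    def rec(self, s, m, score):
        return EvaluationRecord(sample_id=s, method_id=m, score=score)

    def test_summary_mean_sd(self):
        recs = [
            self.rec("s1", "m", 1.0),
            self.rec("s2", "m", 0.0),
            EvaluationRecord(sample_id="s3", method_id="m", excluded=True, reason="x"),
        ]
        row = summarize_records(recs).iloc[0]
        assert row["n"] == 2 and row["n_excluded"] == 1
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(np.std([1.0, 0.0], ddof=1))

    def test_identical_scores_insufficient(self):
        a = [self.rec(f"s{i}", "a", 0.5) for i in range(10)]
        b = [self.rec(f"s{i}", "b", 0.5) for i in range(10)]
        res = compare_methods(a, b)
        assert res.insufficient and res.p_value is None

    def test_strict_dominance_is_significant(self):
        a = [self.rec(f"s{i}", "a", 1.0) for i in range(20)]
        b = [self.rec(f"s{i}", "b", 0.5 + 0.01 * i) for i in range(20)]
        res = compare_methods(a, b)
        assert res.p_value < 0.01

    def test_symmetric_differences_not_significant(self):
        diffs = [0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4]
        a = [self.rec(f"s{i}", "a", 0.5 + d) for i, d in enumerate(diffs)]
        b = [self.rec(f"s{i}", "b", 0.5) for i in range(len(diffs))]
        res = compare_methods(a, b)
        assert res.p_value > 0.9

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a1 = [self.rec(f"s{i}", "a", v) for i, v in enumerate(x)]
        b1 = [self.rec(f"s{i}", "b", v) for i, v in enumerate(y)]
        a2 = [self.rec(f"s{i}", "a", v + 5) for i, v in enumerate(x)]
        b2 = [self.rec(f"s{i}", "b", v + 5) for i, v in enumerate(y)]
        assert compare_methods(a1, b1).p_value == pytest.approx(
            compare_methods(a2, b2).p_value
        )

    def test_pairwise_exclusion(self):
        a = [self.rec(f"s{i}", "a", 1.0 - 0.01 * i) for i in range(10)]
        b = [self.rec(f"s{i}", "b", 0.5) for i in range(9)] + [
            EvaluationRecord(sample_id="s9", method_id="b", excluded=True, reason="x")
        ]
        res = compare_methods(a, b)
        assert res.n_pairs == 9
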