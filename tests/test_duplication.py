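import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgene_atlas.duplication import (
    DuplicationEvent,
    all_vs_all_stats,
    build_families,
    find_events,
    pairwise_stats,
    segmental_duplicates,
    summarize,
    summary_from_counts,
)
from rgene_atlas.seqio import GeneModel
from rgene_atlas.synth import mutate_protein, random_protein


def gene(gid, chrom="chr1", start=1):
    return GeneModel(gid, chrom, start, start + 999, "+", [(start, start + 999)])


class TestPairwiseStats:
    def test_identical(self):
        assert pairwise_stats("ACDEFGHIKL", "ACDEFGHIKL") == (1.0, 1.0)

    def test_three_substitutions_in_ten(self):
        cov, ident = pairwise_stats("ACDEFGHIKL", "ACDWFGHVKY")
        assert cov == 1.0 and ident == pytest.approx(0.7)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = random_protein(rng, 80)
            b = mutate_protein(a, 0.3, rng)
            assert pairwise_stats(a, b) == pytest.approx(pairwise_stats(b, a))


class TestFindEvents:
    def stats(self, pairs):
        return {frozenset(k): v for k, v in pairs.items()}

    def test_boundary_is_strict(self):
        genes = [gene("a"), gene("b", start=500_000)]
        stats = self.stats({("a", "b"): (0.70, 0.90)})
        assert find_events(genes, stats) == []
        stats = self.stats({("a", "b"): (0.71, 0.71)})
        assert len(find_events(genes, stats)) == 1

    def test_tandem_array_of_three_yields_two_events(self):
        genes = [gene("a", start=1), gene("b", start=50_000), gene("c", start=100_000)]
        stats = self.stats(
            {("a", "b"): (0.9, 0.9), ("b", "c"): (0.9, 0.9), ("a", "c"): (0.9, 0.9)}
        )
        events = find_events(genes, stats)
        assert len(events) == 2
        assert {(e.gene_a, e.gene_b) for e in events} == {("a", "b"), ("b", "c")}
        assert all(e.tandem for e in events)

    def test_distant_pairs_all_counted(self):
        genes = [gene("a", start=1), gene("b", start=500_000), gene("c", start=1_000_000)]
        stats = self.stats(
            {("a", "b"): (0.9, 0.9), ("b", "c"): (0.9, 0.9), ("a", "c"): (0.9, 0.9)}
        )
        assert len(find_events(genes, stats)) == 3

    def test_event_invariant_enforced(self):
        with pytest.raises(ValueError):
            DuplicationEvent("a", "b", 0.70, 0.90, False)


class TestBuildFamilies:
    def ev(self, a, b):
        return DuplicationEvent(a, b, 0.9, 0.9, False)

    def test_transitive_closure(self):
        fams = build_families([self.ev("A", "B"), self.ev("B", "C")])
        assert len(fams) == 1 and fams[0].members == {"A", "B", "C"}

    def test_no_events_no_families(self):
        assert build_families([]) == []

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 11), st.integers(0, 11)).filter(lambda t: t[0] != t[1]),
            max_size=20,
        )
    )
    def test_families_are_disjoint_and_conserve_genes(self, edges):
        events = [self.ev(f"g{min(a, b)}", f"g{max(a, b)}") for a, b in edges]
        fams = build_families(events)
        seen = set()
        for f in fams:
            assert len(f.members) >= 2
            assert not (seen & f.members)
            seen |= f.members
        all_ids = {f"g{i}" for i in range(12)}
        summary = summarize(fams, all_ids)
        assert summary.single_genes + summary.multigene_genes == 12


class TestSummarize:
    def test_printed_count_arithmetic(self):
        """49 genes in 20 families out of 126 -> avg 2.45, 38.9%, ratio 0.64."""
        s = summary_from_counts(multigene_genes=49, n_families=20, single_genes=77, max_family_size=7)
        assert s.avg_members_per_family == 2.45
        assert s.pct_multigene == 38.9
        assert s.multi_to_single_ratio == 0.64

    def test_all_singletons(self):
        s = summarize([], {"a", "b", "c"})
        assert s.pct_multigene == 0.0 and s.n_families == 0
        assert s.degenerate and s.avg_members_per_family == 0.0

    def test_one_family_containing_everything(self):
        from rgene_atlas.duplication import GeneFamily

        fam = GeneFamily("fam001", frozenset({"a", "b", "c", "d"}))
        s = summarize([fam], {"a", "b", "c", "d"})
        assert s.avg_members_per_family == 4 and s.pct_multigene == 100.0

    def test_overlapping_families_rejected(self):
        from rgene_atlas.duplication import GeneFamily

        fams = [GeneFamily("f1", frozenset("ab")), GeneFamily("f2", frozenset("bc"))]
        with pytest.raises(ValueError, match="disjoint"):
            summarize(fams, set("abc"))


class TestSegmental:
    def test_cross_chromosome_pair_flagged(self):
        from rgene_atlas.duplication import GeneFamily

        genes = [gene("a", chrom="chr3", start=1), gene("b", chrom="chr4", start=1)]
        fams = [GeneFamily("f1", frozenset({"a", "b"}))]
        assert segmental_duplicates(fams, genes) == [("a", "b")]

    def test_intra_chromosomal_families_give_empty_list(self):
        from rgene_atlas.duplication import GeneFamily

        genes = [gene("a", start=1), gene("b", start=500_000)]
        fams = [GeneFamily("f1", frozenset({"a", "b"}))]
        assert segmental_duplicates(fams, genes) == []


class TestPrefilter:
    def test_prefilter_never_changes_events(self):
        """The score-only prefilter must be conservative: event sets with
        and without it are identical on mixed related/unrelated sets."""
        rng = np.random.default_rng(5)
        proteins = {}
        anc = random_protein(rng, 200)
        for i in range(4):
            proteins[f"fam_{i}"] = mutate_protein(anc, 0.1, rng)
        for i in range(6):
            proteins[f"solo_{i}"] = random_protein(rng, 200)
        genes = [gene(gid, start=1 + 300_000 * k) for k, gid in enumerate(sorted(proteins))]
        with_pf = find_events(genes, all_vs_all_stats(proteins, prefilter=True))
        without = find_events(genes, all_vs_all_stats(proteins, prefilter=False))
        assert with_pf == without
        assert len(with_pf) >= 3  # the planted family is linked


class TestPlantedRecovery:
    def test_planted_families_recovered_exactly(self, small_run):
        gen, res, _ = small_run
        assert sorted(sorted(f.members) for f in res.families) == sorted(
            sorted(f) for f in gen.truth.families
        )

    def test_planted_within_family_identity_exceeds_threshold(self, small_genome):
        gen, _ = small_genome
        for fam in gen.truth.families:
            for a, b in itertools.combinations(sorted(fam), 2):
                cov, ident = pairwise_stats(gen.proteins[a], gen.proteins[b])
                assert cov > 0.75 and ident > 0.70

    def test_planted_segmental_pairs_flagged(self, small_run):
        gen, res, _ = small_run
        assert res.segmental_pairs == gen.truth.segmental_pairs
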