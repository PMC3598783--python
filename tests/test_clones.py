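"""Colony profiling, multi-clone exclusion, founder clustering, co-occurrence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbscreen.clones import (
    ColonyProfile,
    cluster_colonies,
    co_occurrence,
    colony_profile,
    flag_multiclone,
    fraction_matrix,
    jaccard,
)

S = lambda i: ("chr1", 1000 + i * 100, "+")


def _profile(colony_id, *site_ids):
    sites = frozenset(S(i) for i in site_ids)
    return ColonyProfile(colony_id, {s: 1 / len(sites) for s in sites}, sites)


class TestColonyProfile:
    def test_site_at_exactly_one_percent_retained(self):
        # the removal rule is strictly below 1%
        p = colony_profile({S(1): 990, S(2): 10}, "c")
        assert p.retained_sites == {S(1), S(2)}

    def test_site_below_one_percent_removed(self):
        p = colony_profile({S(1): 991, S(2): 9}, "c")
        assert p.retained_sites == {S(1)}

    def test_at_most_ten_sites_kept(self):
        counts = {S(i): 100 + i for i in range(12)}  # all above 1%
        p = colony_profile(counts, "c")
        assert len(p.retained_sites) == 10
        # the two lowest-fraction sites are the ones dropped
        assert S(0) not in p.retained_sites and S(1) not in p.retained_sites

    def test_single_site_colony(self):
        p = colony_profile({S(1): 42}, "c")
        assert p.site_fractions == {S(1): 1.0}

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="no reads"):
            colony_profile({}, "c")

    def test_tie_on_fraction_breaks_to_smaller_coordinate(self):
        counts = {S(i): 10 for i in range(11)}
        p = colony_profile(counts, "c")
        assert S(10) not in p.retained_sites  # largest coordinate dropped


class TestFlagMulticlone:
    def test_union_colony_flagged(self):
        a, b = _profile("A", 1, 2), _profile("B", 3, 4)
        d = _profile("D", 1, 2, 3, 4)
        assert flag_multiclone([a, b, d]) == {"D"}

    def test_identical_colonies_not_flagged(self):
        assert flag_multiclone([_profile("A", 1, 2), _profile("B", 1, 2)]) == set()

    def test_never_flags_exact_duplicate_of_another_colony(self):
        a, b = _profile("A", 1, 2), _profile("B", 3, 4)
        d1 = _profile("D1", 1, 2, 3, 4)
        d2 = _profile("D2", 1, 2, 3, 4)
        flagged = flag_multiclone([a, b, d1, d2])
        sets = {p.colony_id: p.retained_sites for p in (a, b, d1, d2)}
        for name in flagged:
            assert not any(
                sets[name] == other for cid, other in sets.items() if cid != name
            )

    def test_one_missing_site_slack(self):
        a, b = _profile("A", 1, 2, 3), _profile("B", 4, 5, 6)
        d = _profile("D", 1, 2, 4, 5, 6)  # lost site 3 of component A
        assert "D" in flag_multiclone([a, b, d])

    def test_mixed_read_simulation_flagged(self, small_genome):
        # colonies from two founders plus one colony mixing their reads
        from pbscreen.pipeline import genotype_site_counts
        from pbscreen.simulate import SimConfig, make_library

        genome, _ = small_genome
        config = SimConfig(seed=31, n_clones=2, genome_length=1_000_000,
                           n_genes=3, gene_length=10_000,
                           insertions_mean=4.0, insertions_max=5)
        f1, f2 = make_library(genome, config)
        c1 = genotype_site_counts(f1, genome)
        c2 = genotype_site_counts(f2, genome)
        mixed = dict(c1)
        for k, v in c2.items():
            mixed[k] = mixed.get(k, 0) + v
        profiles = [
            colony_profile(c1, "A"),
            colony_profile(c2, "B"),
            colony_profile(mixed, "M"),
        ]
        assert flag_multiclone(profiles) == {"M"}


class TestClusterColonies:
    def test_exact_partition(self):
        founders = cluster_colonies(
            [_profile("A", 1, 2), _profile("B", 1, 2), _profile("C", 3)]
        )
        assert len(founders) == 2
        by_members = {f.member_colonies: f.signature for f in founders}
        assert by_members[frozenset({"A", "B"})] == {S(1), S(2)}
        assert by_members[frozenset({"C"})] == {S(3)}

    def test_pairwise_disjoint_colonies_one_founder_each(self):
        profiles = [_profile(f"c{i}", 3 * i, 3 * i + 1) for i in range(6)]
        assert len(cluster_colonies(profiles)) == 6

    def test_signature_is_union_of_members(self):
        # one colony dropped a site; the cluster signature keeps it
        founders = cluster_colonies([_profile("A", 1, 2, 3), _profile("B", 1, 2)])
        assert len(founders) == 1
        assert founders[0].signature == {S(1), S(2), S(3)}

    @given(st.permutations(range(8)))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_permutation_invariant(self, order):
        base = [
            _profile("A", 1, 2), _profile("B", 1, 2), _profile("C", 3, 4),
            _profile("D", 3, 4, 5), _profile("E", 7), _profile("F", 8, 9),
            _profile("G", 8, 9), _profile("H", 10),
        ]
        reference = cluster_colonies(base)
        shuffled = cluster_colonies([base[i] for i in order])
        assert [(f.signature, f.member_colonies) for f in reference] == [
            (f.signature, f.member_colonies) for f in shuffled
        ]

    def test_planted_partition_recovered(self, small_genome):
        from sklearn.metrics import adjusted_rand_score

        from pbscreen.pipeline import genotype_site_counts
        from pbscreen.simulate import SimConfig, make_library

        genome, _ = small_genome
        config = SimConfig(seed=41, n_clones=5, genome_length=1_000_000,
                           n_genes=3, gene_length=10_000)
        founders = make_library(genome, config)
        rng = np.random.default_rng(4)
        labels, profiles = [], []
        for i in range(15):
            f = int(rng.integers(0, len(founders)))
            labels.append(f)
            counts = genotype_site_counts(founders[f], genome)
            profiles.append(colony_profile(counts, f"colony{i}"))
        clusters = cluster_colonies(profiles)
        assignment = {}
        for ci, f in enumerate(clusters):
            for colony in f.member_colonies:
                assignment[colony] = ci
        predicted = [assignment[f"colony{i}"] for i in range(15)]
        assert adjusted_rand_score(labels, predicted) == 1.0


class TestCoOccurrence:
    def test_driver_and_modifier_pattern(self):
        out = co_occurrence({"F1": {"A"}, "F2": {"A", "M"}, "F3": {"A"}})
        got = dict(zip(out["gene_id"], out["classification"]))
        assert got == {"A": "standalone_driver", "M": "co_occurring_modifier"}
        assert out.set_index("gene_id").loc["M", "drivers"] == "A"

    def test_two_singleton_founders_both_drivers(self):
        out = co_occurrence({"F1": {"X"}, "F2": {"Y"}})
        assert set(out["classification"]) == {"standalone_driver"}

    def test_gene_sometimes_alone_is_driver_not_modifier(self):
        out = co_occurrence({"F1": {"A", "B"}, "F2": {"B"}})
        got = dict(zip(out["gene_id"], out["classification"]))
        assert got["B"] == "standalone_driver"

    def test_matches_brute_force_predicate_oracle(self):
        rng = np.random.default_rng(8)
        genes = list("ABCDE")
        for trial in range(30):
            founder_genes = {
                f"F{i}": set(
                    g for g in genes if rng.random() < 0.4
                ) or {rng.choice(genes)}
                for i in range(int(rng.integers(2, 6)))
            }
            out = co_occurrence(founder_genes)
            got = dict(zip(out["gene_id"], out["classification"]))
            universe = set().union(*founder_genes.values())
            for gene in universe:
                carriers = [f for f, gs in founder_genes.items() if gene in gs]
                if any(founder_genes[f] == {gene} for f in carriers):
                    expected = "standalone_driver"
                elif carriers and any(
                    all(d in founder_genes[f] for f in carriers)
                    for d in universe - {gene}
                ):
                    expected = "co_occurring_modifier"
                else:
                    expected = "unclassified"
                assert got[gene] == expected, (trial, gene, founder_genes)


def test_fraction_matrix_shape():
    profiles = [_profile("A", 1, 2), _profile("B", 2, 3)]
    m = fraction_matrix(profiles)
    assert m.shape == (3, 2)
    assert m.loc[:, "A"].sum() == pytest.approx(1.0)


def test_jaccard_basics():
    assert jaccard(frozenset({1, 2}), frozenset({1, 2})) == 1.0
    assert jaccard(frozenset({1}), frozenset({2})) == 0.0
    assert jaccard(frozenset(), frozenset()) == 1.0
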