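"""Clone library, selection and read simulation against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from pbscreen.genome import GeneAnnotation
from pbscreen.simulate import (
    CloneGenotype,
    SelectionRule,
    SimConfig,
    apply_selection,
    make_library,
    make_sample_sheet,
    simulate_reads,
    truncated_poisson_counts,
    truncated_poisson_pmf,
)


@pytest.fixture(scope="module")
def big_library(small_genome):
    genome, _ = small_genome
    config = SimConfig(seed=21, n_clones=10_000, genome_length=1_000_000,
                       n_genes=3, gene_length=10_000)
    return genome, config, make_library(genome, config)


def test_mean_insertions_per_clone(big_library):
    # counts follow Poisson(6) truncated to [1, 11]; the sample mean over
    # 10^4 clones should sit in [5.8, 6.2]
    _, _, library = big_library
    mean = np.mean([len(c.insertions) for c in library])
    assert 5.8 <= mean <= 6.2
    assert all(1 <= len(c.insertions) <= 11 for c in library)


def test_orientation_balance_degenerate(small_genome):
    genome, _ = small_genome
    config = SimConfig(seed=3, n_clones=200, orientation_balance=1.0,
                       genome_length=1_000_000, n_genes=3, gene_length=10_000)
    library = make_library(genome, config)
    assert all(o == "+" for c in library for _, _, o in c.insertions)


def test_forward_fraction_within_binomial_interval(big_library):
    _, _, library = big_library
    orientations = [o for c in library for _, _, o in c.insertions]
    n = len(orientations)
    forward = sum(o == "+" for o in orientations)
    # 99% binomial interval around 0.5
    half_width = 2.576 * math.sqrt(0.25 / n)
    assert abs(forward / n - 0.5) <= half_width


def test_insertion_sites_are_ttaa(big_library, small_genome):
    genome, _ = small_genome
    _, _, library = big_library
    index = {c: set(map(int, v)) for c, v in genome.ttaa_index.items()}
    for clone in library[:100]:
        for chrom, pos, _ in clone.insertions:
            assert pos in index[chrom]


def _driver(strand: str = "+") -> GeneAnnotation:
    if strand == "+":
        return GeneAnnotation("DRV", "chr1", "+", 200_000, 210_000, 200_000,
                              "resistance_driver")
    return GeneAnnotation("DRV", "chr1", "-", 200_000, 210_000, 209_999,
                          "resistance_driver")


class TestSelection:
    def test_forward_insertion_at_64kb_upstream_survives(self):
        gene = _driver("+")
        clone = CloneGenotype("c1", frozenset({("chr1", 200_000 - 64_000, "+")}))
        survivors, truth = apply_selection([clone], [gene], SelectionRule("DRV"))
        assert survivors == [clone]
        assert truth.loc[0, "survived"]

    def test_reverse_only_upstream_insertions_do_not_survive(self):
        gene = _driver("+")
        clone = CloneGenotype("c1", frozenset({("chr1", 150_000, "-"),
                                               ("chr1", 190_000, "-")}))
        survivors, _ = apply_selection([clone], [gene], SelectionRule("DRV"))
        assert survivors == []

    def test_insertion_beyond_window_does_not_survive(self):
        gene = _driver("+")
        clone = CloneGenotype("c1", frozenset({("chr1", 200_000 - 64_001, "+")}))
        survivors, _ = apply_selection([clone], [gene], SelectionRule("DRV"))
        assert survivors == []

    def test_minus_strand_gene_upstream_is_rightward(self):
        gene = _driver("-")
        surviving = CloneGenotype("c1", frozenset({("chr1", 209_999 + 30_000, "-")}))
        wrong_side = CloneGenotype("c2", frozenset({("chr1", 150_000, "-")}))
        survivors, _ = apply_selection([surviving, wrong_side], [gene],
                                       SelectionRule("DRV"))
        assert survivors == [surviving]

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError, match="NOPE"):
            apply_selection([], [_driver()], SelectionRule("NOPE"))

    def test_survivor_fraction_matches_enumeration_oracle(self, big_library,
                                                          small_genome):
        # per-insertion hit probability enumerated over the TTAA index,
        # then mixed over the truncated-Poisson insertion-count law
        genome, genes = small_genome
        _, config, library = big_library
        driver = next(g for g in genes if g.role == "resistance_driver")
        survivors, _ = apply_selection(library, genes,
                                       SelectionRule(driver.gene_id))
        from pbscreen.simulate import _upstream_window

        lo, hi = _upstream_window(driver, config.activation_window)
        index = genome.ttaa_index[driver.chromosome]
        in_window = int(np.searchsorted(index, hi) - np.searchsorted(index, lo))
        p_hit = 0.5 * in_window / genome.total_ttaa
        ks = np.arange(1, 12)
        pmf = truncated_poisson_pmf(6.0, 1, 11)
        p_survive = float(np.sum(pmf * (1 - (1 - p_hit) ** ks)))
        n = len(library)
        sd = math.sqrt(p_survive * (1 - p_survive) / n)
        assert abs(len(survivors) / n - p_survive) <= 4 * sd


class TestReadSimulation:
    def test_fixed_depth_emits_exact_read_count(self, small_genome, tmp_path):
        genome, genes = small_genome
        config = SimConfig(seed=5, genome_length=1_000_000, n_genes=3,
                           gene_length=10_000, signal_depth_median=150,
                           signal_depth_sigma=0.0, n_background_sites=1,
                           background_mean=1.0)
        ttaa = int(genome.ttaa_index["chr1"][500])
        clone = CloneGenotype("c1", frozenset({("chr1", ttaa, "+")}))
        sheet = make_sample_sheet(["s"], config)
        fastq = tmp_path / "one.fastq"
        sidecar = simulate_reads({"s": [clone]}, genome, sheet, config, fastq)
        signal = sidecar[sidecar["origin"] == "signal"]
        assert len(signal) == 1
        assert int(signal["count"].iloc[0]) == 150
        n_reads = sum(1 for line in open(fastq) if line.startswith("@"))
        assert n_reads == 150 + int(sidecar[sidecar["origin"] == "background"]["count"].sum())

    def test_background_counts_match_truncated_poisson_moment(self):
        # oracle: truncated-Poisson mean by direct summation over [1, 50]
        rng = np.random.default_rng(0)
        draws = truncated_poisson_counts(5.0, 1, 50, 10_000, rng)
        k = np.arange(1, 51)
        pmf = stats.poisson.pmf(k, 5.0)
        pmf /= pmf.sum()
        mean = float(np.sum(k * pmf))
        var = float(np.sum(k**2 * pmf) - mean**2)
        sd_of_mean = math.sqrt(var / len(draws))
        assert abs(draws.mean() - mean) <= 3 * sd_of_mean
        assert draws.min() >= 1 and draws.max() <= 50

    def test_biphasic_count_structure(self, small_screen):
        sidecar = small_screen["sidecar"]
        emitted = sidecar[sidecar["status"] == "ok"]
        background = emitted[emitted["origin"] == "background"]["count"]
        signal = emitted[emitted["origin"] == "signal"]["count"]
        assert background.between(1, 50).all()
        assert (signal >= 100).all()

    def test_same_seed_gives_byte_identical_fastq(self, small_genome, tmp_path):
        genome, _ = small_genome
        config = SimConfig(seed=9, genome_length=1_000_000, n_genes=3,
                           gene_length=10_000, n_background_sites=20)
        ttaa = int(genome.ttaa_index["chr1"][100])
        clone = CloneGenotype("c1", frozenset({("chr1", ttaa, "-")}))
        sheet = make_sample_sheet(["s"], config)
        paths = []
        for tag in ("a", "b"):
            path = tmp_path / f"{tag}.fastq"
            simulate_reads({"s": [clone]}, genome, sheet, config, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_insertion_without_primer_side_site_is_undetectable(self, tmp_path):
        # a sense insertion with no GTAC anywhere to its left cannot be
        # amplified; it must appear in the sidecar with zero reads
        seq = "A" * 30 + "TTAA" + "A" * 30 + "GTAC" + "A" * 30
        from pbscreen.genome import SyntheticGenome

        genome = SyntheticGenome.from_sequences({"chr1": seq})
        config = SimConfig(seed=1, genome_length=100_000, n_background_sites=1,
                           background_mean=1.0)
        clone = CloneGenotype("c1", frozenset({("chr1", 30, "+")}))
        sheet = {"AGTAGT": "s"}
        sidecar = simulate_reads({"s": [clone]}, genome, sheet, config,
                                 tmp_path / "u.fastq")
        undetectable = sidecar[sidecar["status"] == "no_csp6i"]
        assert len(undetectable) == 1
        assert int(undetectable["count"].iloc[0]) == 0

    def test_sidecar_and_fastq_counts_consistent(self, small_screen):
        sidecar = small_screen["sidecar"]
        fastq = small_screen["fastq"]
        n_reads = sum(1 for i, _ in enumerate(open(fastq)) if i % 4 == 0)
        assert n_reads == int(sidecar["count"].sum())


def test_sample_sheet_barcodes_are_valid(small_config):
    sheet = make_sample_sheet([f"s{i}" for i in range(96)], small_config)
    assert len(sheet) == 96
    assert all(len(b) == 6 and set(b) <= set("AGT") for b in sheet)
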