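"""Shared fixtures: a small seeded genome and screen configuration.

Everything is generated programmatically; the small configuration keeps a
full simulate -> demultiplex -> align -> count round trip to a couple of
seconds so it can back several test modules.
"""

from __future__ import annotations

import pytest

from pbscreen.demux import SampleSheet
from pbscreen.pipeline import call_sites_from_fastq
from pbscreen.simulate import (
    SelectionRule,
    SimConfig,
    annotate_detectability,
    apply_selection,
    make_genome,
    make_library,
    make_sample_sheet,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_clones=400,
        n_background_sites=150,
        genome_length=1_000_000,
        n_genes=3,
        gene_length=10_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_screen(small_config, small_genome, tmp_path_factory):
    """One complete small pooled screen with truth annotations."""
    genome, genes = small_genome
    library = make_library(genome, small_config)
    survivors, truth = apply_selection(
        library, genes, SelectionRule(driver_gene="GENE000")
    )
    sheet_map = make_sample_sheet(["pool"], small_config)
    fastq = tmp_path_factory.mktemp("screen") / "pool.fastq"
    sidecar = simulate_reads({"pool": survivors}, genome, sheet_map, small_config, fastq)
    sidecar = annotate_detectability(sidecar, genome, small_config)
    sheet = SampleSheet(sheet_map, small_config.barcode_length)
    site_tables, accounting = call_sites_from_fastq(fastq, sheet, genome, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "library": library,
        "survivors": survivors,
        "selection_truth": truth,
        "sheet_map": sheet_map,
        "sheet": sheet,
        "fastq": fastq,
        "sidecar": sidecar,
        "sites": site_tables["pool"],
        "accounting": accounting,
    }
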