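"""End-to-end orchestration: reads -> sites -> enrichment -> candidates.

Two ready-made flows mirror the two arms of an activation-tagging screen:

* :func:`run_pool_screen` — a pooled screen: mutagenise, select, sequence
  the surviving pool, call and filter sites, and rank candidate genes.
* :func:`run_clonal_screen` — a clonal screen: isolate resistant colonies,
  sequence each with its own barcode, build filtered colony profiles,
  exclude apparent multi-clone colonies, cluster the rest into founder
  clones and classify genes as standalone drivers or co-occurring
  modifiers.

Both return plain dictionaries of intermediate artefacts so tests and
scripts can interrogate every stage.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import clones as _clones
from .align import ExactAligner, MULTI_MAPPED, UNMAPPED
from .demux import SampleSheet, demultiplex, trim
from .enrich import BackgroundModel, filter_sites, fit_background, merge_screens
from .genome import SyntheticGenome
from .sitecall import OFF_SITE, anchor_to_site, count_sites
from .simulate import (
    DEFAULT_ADAPTER,
    CloneGenotype,
    SelectionRule,
    SimConfig,
    apply_selection,
    make_genome,
    make_library,
    make_sample_sheet,
    simulate_reads,
    _primer_side_site,
)


def call_sites_from_fastq(
    fastq_path,
    sheet: SampleSheet,
    genome: SyntheticGenome,
    config: SimConfig,
    adapter: str = DEFAULT_ADAPTER,
    tolerance: int = 3,
    max_mismatch: int = 0,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Demultiplex, trim, align and anchor a FASTQ into per-sample site
    tables plus a per-sample accounting table.

    Identical read sequences are collapsed before alignment (exact-match
    alignment is a pure function of the sequence), so the cost scales with
    distinct sequences while counts conserve the full read totals:
    accepted + off_site + multi_mapped + unmapped = trimmed reads.
    """
    by_sample, unmatched, demux_tallies = demultiplex(fastq_path, sheet, max_mismatch)
    counters: Dict[str, Counter] = {}
    trim_tallies: Dict[str, Dict[str, int]] = {}
    for sample, records in by_sample.items():
        counter: Counter = Counter()
        discards: Dict[str, int] = {}
        for _, seq, _ in records:
            body, reason = trim(
                seq, config.barcode_length, 1, adapter
            )
            if body is None:
                discards[reason] = discards.get(reason, 0) + 1
            else:
                counter[body] += 1
        counters[sample] = counter
        trim_tallies[sample] = discards

    aligner = ExactAligner(genome)
    all_seqs = set()
    for counter in counters.values():
        all_seqs.update(counter)
    mapped = aligner.map_unique(all_seqs)

    site_tables: Dict[str, pd.DataFrame] = {}
    accounting_rows = []
    for sample, counter in counters.items():
        anchored = []
        multiplicities = []
        tally = {"accepted": 0, OFF_SITE: 0, MULTI_MAPPED: 0, UNMAPPED: 0}
        for seq, n in counter.items():
            hit, reason = mapped[seq]
            if hit is None:
                tally[reason] += n
                continue
            key = anchor_to_site(hit, genome.csp6i_index, tolerance)
            if key is None:
                tally[OFF_SITE] += n
                continue
            anchored.append((*key, sample))
            multiplicities.append(n)
            tally["accepted"] += n
        site_tables[sample] = count_sites(anchored, multiplicities)
        accounting_rows.append(
            (
                sample,
                int(sum(counter.values())),
                tally["accepted"],
                tally[OFF_SITE],
                tally[MULTI_MAPPED],
                tally[UNMAPPED],
                trim_tallies[sample].get("too_short_pretrim", 0),
                trim_tallies[sample].get("too_short_posttrim", 0),
            )
        )
    accounting = pd.DataFrame(
        accounting_rows,
        columns=["sample_id", "trimmed_reads", "accepted", OFF_SITE,
                 MULTI_MAPPED, UNMAPPED, "too_short_pretrim", "too_short_posttrim"],
    )
    return site_tables, accounting


def run_pool_screen(
    config: SimConfig,
    workdir,
    driver_gene: str = "GENE000",
    cell_line: str = "LINE1",
    threshold_mode: str = "fixed_threshold",
) -> Dict:
    """Simulate and analyse one pooled screen, returning every stage.

    The surviving clones are sequenced as a single pooled sample; sites are
    filtered with the chosen threshold mode, collapsed into independent
    events (single screen, so the collapse is trivial), assigned to genes
    within 25 kb, and tallied into the ranked candidate table.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    genome, genes = make_genome(config)
    library = make_library(genome, config)
    rule = SelectionRule(driver_gene=driver_gene, window_kb=config.activation_window_kb)
    survivors, truth = apply_selection(library, genes, rule)

    sample_id = f"{cell_line}_pool"
    sheet_map = make_sample_sheet([sample_id], config)
    sheet = SampleSheet(sheet_map, config.barcode_length)
    fastq = workdir / "pool.fastq"
    sidecar = simulate_reads({sample_id: survivors}, genome, sheet_map, config, fastq)

    site_tables, accounting = call_sites_from_fastq(fastq, sheet, genome, config)
    sites = site_tables[sample_id]

    if threshold_mode == "fixed_threshold":
        model = BackgroundModel(mu=None, mode="fixed_threshold")
    else:
        model = fit_background(sites["count"].to_numpy())
    enriched = filter_sites(sites, model)
    passed = enriched[enriched["passed"]]

    events = merge_screens([("lib1", "A", passed)])
    events = events.rename(columns={"total_reads": "total_reads"})
    events["cell_line"] = cell_line
    annotated = _annotate.assign_genes(events, genes, window_kb=25.0,
                                       activation_window_kb=config.activation_window_kb)
    gene_table, membership = _annotate.gene_tally(annotated)
    return {
        "genome": genome,
        "genes": genes,
        "library": library,
        "survivors": survivors,
        "selection_truth": truth,
        "sidecar": sidecar,
        "sites": sites,
        "accounting": accounting,
        "model": model,
        "enriched": enriched,
        "events": events,
        "annotated": annotated,
        "gene_table": gene_table,
        "membership": membership,
    }


def sample_colonies(
    survivors: Sequence[CloneGenotype], n_colonies: int, rng: np.random.Generator
) -> List[CloneGenotype]:
    """Pick resistant colonies from the surviving clones, with replacement:
    one founder clone can seed several colonies."""
    if not survivors:
        raise ValueError("no surviving clones to pick colonies from")
    idx = rng.integers(0, len(survivors), size=n_colonies)
    return [survivors[i] for i in idx]


def genotype_site_counts(
    clone: CloneGenotype,
    genome: SyntheticGenome,
    depth: int = 300,
) -> Dict[Tuple[str, int, str], int]:
    """Noise-free per-site counts a colony of this genotype would produce:
    each insertion maps to its primer-side Csp6I site at fixed depth."""
    counts: Dict[Tuple[str, int, str], int] = {}
    for chrom, ttaa, orient in sorted(clone.insertions):
        anchored = _primer_side_site(ttaa, orient, genome.csp6i_index[chrom])
        if anchored is None:
            continue
        gtac, strand = anchored
        key = (chrom, gtac, strand)
        counts[key] = counts.get(key, 0) + depth
    return counts


def run_clonal_screen(
    config: SimConfig,
    workdir,
    driver_gene: str = "GENE000",
    modifier_gene: str = "GENE001",
    n_colonies: int = 24,
    jaccard_min: float = 0.5,
    annotation_window_kb: float = 66.0,
) -> Dict:
    """Simulate and analyse a clonal screen under a cooperative rule.

    Selection requires both an activating insertion upstream of the driver
    and any insertion in the modifier's gene body.  Isolated colonies are
    sequenced with individual barcodes, profiled (<1% sites removed, top
    1-10 kept), screened for multi-clone mixtures, clustered into founders
    and their gene signatures classified by co-occurrence.  Founder
    signatures are annotated with the activation window so that upstream
    activating sites map to the genes they drive; the default window is
    padded by 2 kb because a site's Csp6I anchor sits slightly further
    from the gene than the insertion itself.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    genome, genes = make_genome(config)
    library = make_library(genome, config)
    rule = SelectionRule(
        driver_gene=driver_gene,
        window_kb=config.activation_window_kb,
        modifier_gene=modifier_gene,
    )
    survivors, truth = apply_selection(library, genes, rule)
    if not survivors:
        raise RuntimeError("cooperative selection left no survivors")
    rng = np.random.default_rng([23, config.seed])
    colonies = sample_colonies(survivors, n_colonies, rng)

    samples = {f"colony{i:03d}": [clone] for i, clone in enumerate(colonies)}
    sheet_map = make_sample_sheet(sorted(samples), config)
    sheet = SampleSheet(sheet_map, config.barcode_length)
    fastq = workdir / "colonies.fastq"
    sidecar = simulate_reads(samples, genome, sheet_map, config, fastq)

    site_tables, accounting = call_sites_from_fastq(fastq, sheet, genome, config)
    profiles = []
    for colony_id in sorted(samples):
        table = site_tables[colony_id]
        if len(table) == 0:
            continue
        counts = {
            (r.chromosome, int(r.csp6i_coordinate), r.read_strand): int(r.count)
            for r in table.itertuples(index=False)
        }
        profiles.append(_clones.colony_profile(counts, colony_id))

    excluded = _clones.flag_multiclone(profiles, jaccard_min)
    kept = [p for p in profiles if p.colony_id not in excluded]
    founders = _clones.cluster_colonies(kept, jaccard_min)

    founder_genes: Dict[str, set] = {}
    for f in founders:
        sites = pd.DataFrame(
            sorted(f.signature), columns=["chromosome", "csp6i_coordinate", "read_strand"]
        )
        annotated = _annotate.assign_genes(
            sites, genes, window_kb=annotation_window_kb,
            activation_window_kb=config.activation_window_kb,
        )
        founder_genes[f.founder_id] = set(annotated["gene_id"].dropna())
    classification = _clones.co_occurrence(founder_genes)
    return {
        "genome": genome,
        "genes": genes,
        "survivors": survivors,
        "colonies": colonies,
        "sidecar": sidecar,
        "accounting": accounting,
        "profiles": profiles,
        "excluded": excluded,
        "founders": founders,
        "founder_genes": founder_genes,
        "classification": classification,
    }
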