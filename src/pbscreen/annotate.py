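"""Gene assignment, effect prediction and gene-level candidate tables.

An insertion event is assigned to every gene whose span, extended by a
25 kb window on both sides, contains the event coordinate — the working
range for linking insertions to the genes they may regulate.  Assignment is
deliberately many-to-many: one event can annotate several genes, and events
hitting no gene are kept unassigned (they may mark non-coding elements).

Orientation is classified relative to the gene: ``sense`` means the
transposon's promoter points in the gene's transcriptional direction.
Position is ``upstream`` (5' of the gene span), ``intragenic`` or
``downstream``; upstream distances are measured to the first coding base,
downstream distances to the annotated gene end (a stand-in for the
poly-adenylation site).  A sense upstream insertion within the activation
range (default 64 kb, the longest distance at which activation has been
observed) predicts ``activation``; intragenic insertions of either
orientation predict ``disruption``; everything else is ``ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneAnnotation
from .sitecall import SITE_KEY

ORIENTATIONS = ("sense", "antisense")
POSITIONS = ("upstream", "intragenic", "downstream")
EFFECTS = ("activation", "disruption", "ambiguous")

ANNOTATION_COLUMNS = [
    *SITE_KEY, "gene_id", "orientation", "position",
    "distance_to_cds_start", "predicted_effect",
]


def classify_position(
    coordinate: int, gene: GeneAnnotation
) -> Tuple[str, Optional[int]]:
    """Position of a coordinate relative to a gene, with the distance
    convention described in the module docstring.  Distance is defined only
    for upstream/downstream positions."""
    if gene.start <= coordinate < gene.end:
        return "intragenic", None
    if gene.strand == "+":
        if coordinate < gene.start:
            return "upstream", gene.cds_start - coordinate
        return "downstream", coordinate - (gene.end - 1)
    if coordinate >= gene.end:
        return "upstream", coordinate - gene.cds_start
    return "downstream", gene.start - coordinate


def predict_effect(
    orientation: str,
    position: str,
    distance_to_cds_start: Optional[int],
    activation_window_kb: float = 64.0,
) -> str:
    """Predicted transcriptional consequence of one annotated insertion.

    Pure and total over (orientation, position, distance): sense + upstream
    within the activation window -> activation; intragenic -> disruption;
    anything else -> ambiguous.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}")
    if position == "intragenic":
        return "disruption"
    if (
        orientation == "sense"
        and position == "upstream"
        and distance_to_cds_start is not None
        and distance_to_cds_start <= activation_window_kb * 1000
    ):
        return "activation"
    return "ambiguous"


def assign_genes(
    events: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    window_kb: float = 25.0,
    activation_window_kb: float = 64.0,
) -> pd.DataFrame:
    """Assign insertion events to genes within ``window_kb`` of their span.

    ``events`` needs the site key columns (chromosome, csp6i_coordinate,
    read_strand); the read strand doubles as the insertion orientation on
    the reference.  Returns one row per (event, gene) pair plus one
    unassigned row (gene_id NaN) per event with no gene in range.
    """
    window = int(round(window_kb * 1000))
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start - window, g.end + window, g
        )
    extra = [c for c in events.columns if c not in SITE_KEY]
    rows = []
    for ev in events.itertuples(index=False):
        chrom = ev.chromosome
        coord = int(ev.csp6i_coordinate)
        strand = ev.read_strand
        carried = tuple(getattr(ev, c) for c in extra)
        hits = trees[chrom][coord] if chrom in trees else set()
        if not hits:
            rows.append((chrom, coord, strand, None, None, None, None, None) + carried)
            continue
        for iv in sorted(hits, key=lambda iv: iv.data.gene_id):
            gene: GeneAnnotation = iv.data
            position, distance = classify_position(coord, gene)
            orientation = "sense" if strand == gene.strand else "antisense"
            effect = predict_effect(orientation, position, distance, activation_window_kb)
            rows.append(
                (chrom, coord, strand, gene.gene_id, orientation, position,
                 distance, effect) + carried
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + extra)


def gene_tally(annotated: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, Set[str]]]:
    """Aggregate annotated events into a gene-level candidate table.

    Expects the output of :func:`assign_genes`, ideally carrying
    ``total_reads`` and ``cell_line`` columns.  Returns the per-gene table
    ranked by (number of cell lines, number of independent insertion sites,
    total reads) descending, plus per-cell-line gene membership sets for
    Venn-style reporting.  Recurrence strata (>=2, >=3 independent
    insertions) are flagged as boolean columns.
    """
    hits = annotated.dropna(subset=["gene_id"]).copy()
    if len(hits) == 0:
        empty = pd.DataFrame(
            columns=["gene_id", "n_independent_insertions", "total_reads",
                     "n_cell_lines", "cell_lines", "recurrent_2", "recurrent_3"]
        )
        return empty, {}
    if "cell_line" not in hits.columns:
        hits["cell_line"] = "NA"
    if "total_reads" not in hits.columns:
        hits["total_reads"] = 0
    hits["site_key"] = list(
        zip(hits["chromosome"], hits["csp6i_coordinate"], hits["read_strand"])
    )
    # an independent insertion = one (library, site key) event; events frame
    # already collapsed replicates, so distinct rows per gene count events
    grouped = hits.groupby("gene_id")
    table = pd.DataFrame(
        {
            "n_independent_insertions": grouped["site_key"].size(),
            "n_distinct_sites": grouped["site_key"].nunique(),
            "total_reads": grouped["total_reads"].sum(),
            "n_cell_lines": grouped["cell_line"].nunique(),
            "cell_lines": grouped["cell_line"].apply(
                lambda s: ";".join(sorted(set(s)))
            ),
        }
    ).reset_index()
    table["recurrent_2"] = table["n_independent_insertions"] >= 2
    table["recurrent_3"] = table["n_independent_insertions"] >= 3
    table = table.sort_values(
        ["n_cell_lines", "n_independent_insertions", "total_reads", "gene_id"],
        ascending=[False, False, False, True],
        ignore_index=True,
    )
    membership: Dict[str, Set[str]] = {
        line: set(sub["gene_id"])
        for line, sub in hits.groupby("cell_line")
    }
    return table, membership


def bubble_export(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready gene summary (gene, insertions, reads, cell lines)."""
    return table[
        ["gene_id", "n_independent_insertions", "total_reads", "n_cell_lines"]
    ].copy()
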