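"""Anchor unique alignments to Csp6I cut sites and count reads per site.

Csp6I recognises ``G^TAC`` and leaves a 2 nt 5' TA overhang, so the enzyme
cuts the top strand after the G and the bottom strand after the (bottom
strand) G.  With ``g`` the 0-based start of a GTAC motif, the first base of
the downstream restriction fragment sits at ``g + 1`` on the plus strand and
at ``g + 3`` on the minus strand.  Those two coordinates are where the 5'
ends of splinkerette reads pile up, and both the read simulator and this
module use them as the single cut convention.

A unique alignment is accepted when its 5' coordinate lies within
``tolerance`` (default 3) bases of a cut on the read's strand; ties between
equidistant sites break toward the smaller motif coordinate so the
assignment is deterministic.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .align import AlignmentHit

#: reason label for unique alignments that anchor to no Csp6I cut
OFF_SITE = "off_site"

_CUT_OFFSET = {"+": 1, "-": 3}

#: column order of a site-count table
SITE_COLUMNS = ["chromosome", "csp6i_coordinate", "read_strand", "sample_id", "count"]

#: the (site, strand) identity of an insertion event
SITE_KEY = ["chromosome", "csp6i_coordinate", "read_strand"]


def cut_coordinate(gtac_start: int, strand: str) -> int:
    """Coordinate of the first fragment base left by the Csp6I cut on the
    given strand, for a motif starting at ``gtac_start``."""
    return gtac_start + _CUT_OFFSET[strand]


def anchor_to_site(
    hit: AlignmentHit,
    csp6i_index: Dict[str, np.ndarray],
    tolerance: int = 3,
) -> Optional[Tuple[str, int, str]]:
    """Assign a unique alignment to the nearest Csp6I site on its strand.

    Returns the site key ``(chromosome, gtac_start, read_strand)`` or
    ``None`` when no cut on the read's strand lies within ``tolerance``
    bases of the read's 5' end.
    """
    motifs = csp6i_index.get(hit.chromosome)
    if motifs is None or len(motifs) == 0:
        return None
    target = hit.five_prime_coordinate - _CUT_OFFSET[hit.strand]
    i = int(np.searchsorted(motifs, target))
    best: Optional[int] = None
    best_dist: Optional[int] = None
    for j in (i - 1, i):  # nearest motif is one of the two flanking entries
        if 0 <= j < len(motifs):
            dist = abs(int(motifs[j]) - target)
            # ties break toward the smaller coordinate: strict < keeps the
            # earlier (smaller) candidate when distances are equal
            if best_dist is None or dist < best_dist:
                best, best_dist = int(motifs[j]), dist
    if best is None or best_dist > tolerance:
        return None
    return (hit.chromosome, best, hit.strand)


def count_sites(
    anchored: Iterable[Tuple[str, int, str, str]],
    multiplicities: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Aggregate anchored reads into a per-sample per-site count table.

    ``anchored`` yields ``(chromosome, gtac_start, read_strand, sample_id)``
    once per read, or once per distinct read sequence when
    ``multiplicities`` supplies the number of identical reads behind each
    entry.  Total counts conserve the number of accepted reads.
    """
    counter: Counter = Counter()
    if multiplicities is None:
        for key in anchored:
            counter[key] += 1
    else:
        for key, m in zip(anchored, multiplicities):
            counter[key] += int(m)
    rows = [
        (chrom, coord, strand, sample, n)
        for (chrom, coord, strand, sample), n in counter.items()
    ]
    table = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return table.sort_values(SITE_COLUMNS[:4], ignore_index=True)


def sites_to_bed(table: pd.DataFrame) -> pd.DataFrame:
    """Export a site table as BED6: the cut position as a 1-base interval,
    the count as score, the read strand as strand."""
    cut = [
        cut_coordinate(int(c), s)
        for c, s in zip(table["csp6i_coordinate"], table["read_strand"])
    ]
    return pd.DataFrame(
        {
            "chrom": table["chromosome"],
            "start": cut,
            "end": [c + 1 for c in cut],
            "name": [
                f"{s}:{ch}:{co}"
                for s, ch, co in zip(
                    table["sample_id"], table["chromosome"], table["csp6i_coordinate"]
                )
            ],
            "score": table["count"],
            "strand": table["read_strand"],
        }
    )


def write_sites(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
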