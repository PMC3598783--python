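"""Poisson library-coverage design and insertion-library statistics.

Sizing an activation-tagging library is a coverage problem: only
sense-orientation insertions within the activation window (default 64 kb)
upstream of a gene can activate it, and insertions land essentially at
random, so the number of activating insertions a gene receives is Poisson.
To activate a gene with probability ``1 - miss_prob`` the Poisson mean of
activating insertions per window must satisfy
``P(X <= min_hits - 1 | lambda) <= miss_prob``; the required mean then
fixes the genomic spacing of activating insertions
(``gap = window / lambda``), the total insertions needed
(``strand_factor * genome / gap``, the factor 2 accounting for the half of
insertions in the non-activating orientation), and the number of clones
(``insertions / mean insertions per clone``).

Two conventions for the required mean coexist: a 0.01-step upward grid
scan (matching how the headline design means 3.0 and 4.75 are quoted) and
the continuous root of the tail equation (used when un-rounded values feed
downstream arithmetic).  Headline numbers are rounded to two significant
figures at the reporting layer only, sequentially (clones are derived from
the already-rounded insertion count, the way such figures are quoted); raw
values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome import GeneAnnotation, SyntheticGenome
from .sitecall import cut_coordinate


def poisson_lower_tail(k: int, lam: float) -> float:
    """P(X <= k | lam) by direct summation of the mass function."""
    if k < 0:
        return 0.0
    term = math.exp(-lam)
    total = term
    for i in range(1, k + 1):
        term *= lam / i
        total += term
    return total


def required_mean_grid(
    min_hits: int = 1, miss_prob: float = 0.05, step: float = 0.01
) -> float:
    """Smallest Poisson mean on the grid {step, 2*step, ...} for which the
    probability of fewer than ``min_hits`` occurrences is at most
    ``miss_prob``."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if not 0 < miss_prob < 1:
        raise ValueError("miss_prob must lie in (0, 1)")
    i = 1
    while True:
        lam = i * step
        if poisson_lower_tail(min_hits - 1, lam) <= miss_prob:
            return round(lam, 10)
        i += 1


def required_mean_exact(
    min_hits: int = 1, miss_prob: float = 0.05, tol: float = 1e-9
) -> float:
    """Continuous Poisson mean solving P(X <= min_hits-1 | lam) = miss_prob,
    found by bracketed root search on [1e-6, 100]."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if not 0 < miss_prob < 1:
        raise ValueError("miss_prob must lie in (0, 1)")

    def f(lam: float) -> float:
        return poisson_lower_tail(min_hits - 1, lam) - miss_prob

    lo, hi = 1e-6, 100.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("root not bracketed on [1e-6, 100]")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def round_2sf(x: float) -> float:
    """Round to two significant figures, half away from zero."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    shift = d.adjusted() - 1  # exponent of the second significant digit
    quantum = Decimal(1).scaleb(shift)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class CoverageDesign:
    """Inputs and outputs of the library-coverage calculation."""

    window_kb: float = 64.0
    genome_kb: float = 3.0e6
    strand_factor: float = 2.0
    min_hits: int = 1
    miss_prob: float = 0.05
    mean_per_clone: float = 6.0
    mean_mode: str = "grid"  # "grid" or "exact"
    # outputs
    required_mean: float = field(default=float("nan"))
    gap_kb: float = field(default=float("nan"))
    total_insertions: float = field(default=float("nan"))
    total_clones: float = field(default=float("nan"))

    def headline(self) -> Dict[str, float]:
        """Two-significant-figure report, derived sequentially: the clone
        count comes from the rounded insertion count."""
        insertions = round_2sf(self.total_insertions)
        return {
            "required_mean": self.required_mean,
            "gap_kb": round(self.gap_kb, 1),
            "total_insertions": insertions,
            "total_clones": round_2sf(insertions / self.mean_per_clone),
        }


def design_library(
    window_kb: float = 64.0,
    genome_kb: float = 3.0e6,
    strand_factor: float = 2.0,
    min_hits: int = 1,
    miss_prob: float = 0.05,
    mean_per_clone: float = 6.0,
    mean_mode: str = "grid",
) -> CoverageDesign:
    """Complete a coverage design from its inputs.

    ``strand_factor=2`` encodes the balanced-orientation default (only one
    orientation activates, so twice as many insertions are laid down as
    activating ones); set 1 for constructs activating in both orientations.
    """
    for name, value in (
        ("window_kb", window_kb), ("genome_kb", genome_kb),
        ("strand_factor", strand_factor), ("mean_per_clone", mean_per_clone),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if mean_mode == "grid":
        lam = required_mean_grid(min_hits, miss_prob)
    elif mean_mode == "exact":
        lam = required_mean_exact(min_hits, miss_prob)
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    gap = window_kb / lam
    insertions = strand_factor * genome_kb / gap
    clones = insertions / mean_per_clone
    return CoverageDesign(
        window_kb=window_kb,
        genome_kb=genome_kb,
        strand_factor=strand_factor,
        min_hits=min_hits,
        miss_prob=miss_prob,
        mean_per_clone=mean_per_clone,
        mean_mode=mean_mode,
        required_mean=lam,
        gap_kb=gap,
        total_insertions=insertions,
        total_clones=clones,
    )


@dataclass
class LibraryStats:
    """Summary statistics of an insertion-site library."""

    n_sites: int
    ttaa_total: int
    fraction_of_ttaa: float
    mean_gap_kb: float
    gap_quantiles_kb: Dict[float, float]
    intragenic_fraction: float
    near_gene_fraction: float


def library_stats(
    sites: pd.DataFrame,
    genome: SyntheticGenome,
    genes: Sequence[GeneAnnotation],
    near_kb: float = 25.0,
    gap_quantiles: Sequence[float] = (0.5, 0.95, 0.995),
) -> LibraryStats:
    """Characterise an insertion-site table against its genome.

    Gaps are successive differences of distinct sorted cut coordinates per
    chromosome; fractions are of distinct site positions.  An empty table
    yields NaN fractions (explicit not-a-value markers).
    """
    ttaa_total = genome.total_ttaa
    if len(sites) == 0:
        nan = float("nan")
        return LibraryStats(0, ttaa_total, nan, nan,
                            {q: nan for q in gap_quantiles}, nan, nan)
    cuts = pd.DataFrame(
        {
            "chromosome": sites["chromosome"],
            "position": [
                cut_coordinate(int(c), s)
                for c, s in zip(sites["csp6i_coordinate"], sites["read_strand"])
            ],
        }
    ).drop_duplicates()
    gaps: list = []
    for _, sub in cuts.groupby("chromosome"):
        pos = np.sort(sub["position"].to_numpy())
        if len(pos) > 1:
            gaps.extend(np.diff(pos))
    gaps_kb = np.asarray(gaps, dtype=float) / 1000.0
    near = int(round(near_kb * 1000))
    intragenic = 0
    near_gene = 0
    by_chrom: Dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for row in cuts.itertuples(index=False):
        gs = by_chrom.get(row.chromosome, [])
        if any(g.start <= row.position < g.end for g in gs):
            intragenic += 1
        if any(g.start - near <= row.position < g.end + near for g in gs):
            near_gene += 1
    n = len(cuts)
    return LibraryStats(
        n_sites=n,
        ttaa_total=ttaa_total,
        fraction_of_ttaa=n / ttaa_total if ttaa_total else float("nan"),
        mean_gap_kb=float(gaps_kb.mean()) if len(gaps_kb) else float("nan"),
        gap_quantiles_kb={
            q: (float(np.quantile(gaps_kb, q)) if len(gaps_kb) else float("nan"))
            for q in gap_quantiles
        },
        intragenic_fraction=intragenic / n,
        near_gene_fraction=near_gene / n,
    )


def intragenic_ttaa_fraction(
    genome: SyntheticGenome, genes: Sequence[GeneAnnotation]
) -> float:
    """Fraction of all TTAA motifs lying inside a gene span — the null
    expectation against which an observed intragenic site fraction is
    judged (no insertion preference means the two should agree)."""
    total = 0
    inside = 0
    by_chrom: Dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, index in genome.ttaa_index.items():
        total += len(index)
        for g in by_chrom.get(chrom, []):
            lo = np.searchsorted(index, g.start)
            hi = np.searchsorted(index, g.end)
            inside += int(hi - lo)
    return inside / total if total else float("nan")
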