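"""Synthetic genomes, motif indices, and gene annotations.

A piggyBac activation-tagging screen is anchored on two sequence motifs:
``TTAA``, the tetranucleotide the transposon integrates into, and ``GTAC``,
the Csp6I recognition site whose cut positions anchor the 5' ends of
splinkerette sequencing reads.  :class:`SyntheticGenome` keeps both motif
indices alongside the raw sequence so that simulation and site calling share
one coordinate frame (0-based, half-open throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TTAA = "TTAA"
CSP6I_MOTIF = "GTAC"

#: genomic roles a synthetic gene can play in a selection scenario
GENE_ROLES = ("resistance_driver", "modifier", "passenger")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def scan_motif(seq: str, motif: str) -> np.ndarray:
    """Return the sorted 0-based start coordinates of every occurrence of
    ``motif`` in ``seq`` (overlapping occurrences included)."""
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    n = len(a) - len(m) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = a[: n] == m[0]
    for j in range(1, len(m)):
        mask = mask & (a[j : n + j] == m[j])
    return np.flatnonzero(mask).astype(np.int64)


@dataclass
class GeneAnnotation:
    """A gene model on the synthetic genome.

    ``cds_start`` is the genomic coordinate of the first coding base; for a
    minus-strand gene that base sits at the right edge of the span.  The
    ``role`` label records what the gene does in a simulated selection:
    exactly one gene per scenario is the ``resistance_driver``.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cds_start: int
    role: str = "passenger"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError("gene span requires start < end")
        if not (self.start <= self.cds_start < self.end):
            raise ValueError("cds_start must lie within [start, end)")
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")


@dataclass
class SyntheticGenome:
    """Nucleotide sequences plus per-chromosome TTAA and Csp6I indices."""

    chromosomes: Dict[str, str]
    ttaa_index: Dict[str, np.ndarray] = field(default_factory=dict)
    csp6i_index: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, chromosomes: Mapping[str, str]) -> "SyntheticGenome":
        """Build a genome from raw sequences, scanning both motif indices."""
        chroms = {name: str(seq).upper() for name, seq in chromosomes.items()}
        g = cls(chromosomes=chroms)
        g.reindex()
        return g

    def reindex(self) -> None:
        """(Re)scan both motif indices from the stored sequences."""
        self.ttaa_index = {n: scan_motif(s, TTAA) for n, s in self.chromosomes.items()}
        self.csp6i_index = {
            n: scan_motif(s, CSP6I_MOTIF) for n, s in self.chromosomes.items()
        }

    def validate(self) -> None:
        """Check the structural invariants: ACGT alphabet, strictly
        increasing indices, every indexed coordinate pointing at its motif."""
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name}: sequence contains non-ACGT characters")
            for motif, index in ((TTAA, self.ttaa_index), (CSP6I_MOTIF, self.csp6i_index)):
                coords = index[name]
                if np.any(np.diff(coords) <= 0):
                    raise ValueError(f"{name}: {motif} index not strictly increasing")
                for c in coords:
                    if seq[c : c + 4] != motif:
                        raise ValueError(f"{name}:{c} does not spell {motif}")

    @property
    def total_ttaa(self) -> int:
        return int(sum(len(v) for v in self.ttaa_index.values()))

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SyntheticGenome":
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls.from_sequences(chroms)


# --- gene table I/O -------------------------------------------------------
#
# Genes travel as a BED-like TSV: chrom, start, end, gene_id, score, strand,
# cds_start, role.  Coordinates are 0-based half-open, matching BED.

_GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand", "cds_start", "role"]


def genes_to_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    rows = [
        (g.chromosome, g.start, g.end, g.gene_id, 0, g.strand, g.cds_start, g.role)
        for g in genes
    ]
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def frame_to_genes(frame: pd.DataFrame) -> List[GeneAnnotation]:
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            chromosome=str(r.chrom),
            strand=str(r.strand),
            start=int(r.start),
            end=int(r.end),
            cds_start=int(r.cds_start),
            role=str(r.role),
        )
        for r in frame.itertuples(index=False)
    ]


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> List[GeneAnnotation]:
    return frame_to_genes(pd.read_csv(path, sep="\t"))
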