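"""Exact-match unique alignment of trimmed splinkerette reads.

The site-calling contract requires that a read be kept only when its
sequence occurs exactly once across both strands of the reference, with no
mismatches.  On the synthetic genomes used here that contract is met by an
exact substring search; any external aligner producing the same
(coordinate of 5' base, strand, uniqueness) triple can be substituted
behind :func:`align_unique` for real data.

Two code paths implement the same contract:

* :func:`align_unique` — straightforward ``str``-scan of every chromosome,
  used for single reads and as the reference path in tests.
* :class:`ExactAligner` — batch path used by the pipeline.  Each pattern is
  seeded by its first ``seed_k`` bases, encoded as an exact 2-bit-packed
  integer; genome positions whose packed ``seed_k``-mer equals a seed are
  then verified by direct string comparison, so seeding cannot produce a
  wrong answer, only candidates.  Reads shorter than the seed fall back to
  the exhaustive scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .genome import SyntheticGenome, revcomp

#: outcome labels for reads that produce no usable hit
UNMAPPED = "unmapped"
MULTI_MAPPED = "multi_mapped"

# 2-bit base codes; non-ACGT bases map to 0 and are caught at verification
_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class AlignmentHit:
    """A unique exact alignment: coordinate of the read's 5' base on the
    reference and the strand it matched."""

    chromosome: str
    five_prime_coordinate: int
    strand: str
    unique: bool = True


def _occurrences(text: str, pattern: str) -> List[int]:
    """All start offsets of ``pattern`` in ``text`` (overlaps included)."""
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def align_unique(seq: str, genome: SyntheticGenome) -> Tuple[Optional[AlignmentHit], str]:
    """Align one read by exhaustive scan.

    Returns ``(hit, "ok")`` when the sequence occurs exactly once across
    both strands, otherwise ``(None, reason)`` with reason ``unmapped`` or
    ``multi_mapped``.
    """
    rc = revcomp(seq)
    hits: List[AlignmentHit] = []
    for name, text in genome.chromosomes.items():
        for pos in _occurrences(text, seq):
            hits.append(AlignmentHit(name, pos, "+"))
        for pos in _occurrences(text, rc):
            hits.append(AlignmentHit(name, pos + len(seq) - 1, "-"))
    if len(hits) == 1:
        return hits[0], "ok"
    return None, (UNMAPPED if not hits else MULTI_MAPPED)


def _packed_words(text: str, k: int) -> np.ndarray:
    """2-bit-packed value of every length-``k`` window of ``text``."""
    codes = _CODE[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out <<= 2
        out |= codes[j : j + n]
    return out


def _pack(pattern: str) -> int:
    value = 0
    for ch in pattern:
        value = (value << 2) | int(_CODE[ord(ch)])
    return value


class ExactAligner:
    """Batch exact-match aligner over a :class:`SyntheticGenome`.

    ``seed_k`` must satisfy ``seed_k <= 31`` (the packed seed word lives in
    a signed 64-bit integer).
    """

    def __init__(self, genome: SyntheticGenome, seed_k: int = 20):
        if not 1 <= seed_k <= 31:
            raise ValueError("seed_k must lie in [1, 31]")
        self.genome = genome
        self.seed_k = seed_k
        self._word_cache: Dict[str, np.ndarray] = {}

    def _chrom_words(self, name: str) -> np.ndarray:
        if name not in self._word_cache:
            self._word_cache[name] = _packed_words(
                self.genome.chromosomes[name], self.seed_k
            )
        return self._word_cache[name]

    def map_unique(
        self, seqs: Iterable[str]
    ) -> Dict[str, Tuple[Optional[AlignmentHit], str]]:
        """Map every distinct sequence; returns ``seq -> (hit|None, reason)``."""
        unique = sorted(set(seqs))
        results: Dict[str, Tuple[Optional[AlignmentHit], str]] = {}

        long_reads = [s for s in unique if len(s) >= self.seed_k]
        short_reads = [s for s in unique if len(s) < self.seed_k]
        for s in short_reads:
            results[s] = align_unique(s, self.genome)
        if not long_reads:
            return results

        # one (pattern text, owner read, strand) entry per search direction
        patterns: List[Tuple[str, str, str]] = []
        for s in long_reads:
            patterns.append((s, s, "+"))
            patterns.append((revcomp(s), s, "-"))
        seed_to_patterns: Dict[int, List[int]] = defaultdict(list)
        for idx, (pat, _, _) in enumerate(patterns):
            seed_to_patterns[_pack(pat[: self.seed_k])].append(idx)
        wanted = np.array(sorted(seed_to_patterns), dtype=np.int64)

        occurrences: Dict[str, List[AlignmentHit]] = defaultdict(list)
        for name, text in self.genome.chromosomes.items():
            words = self._chrom_words(name)
            if not len(words):
                continue
            loc = np.searchsorted(wanted, words)
            loc[loc == len(wanted)] = 0
            candidate_pos = np.flatnonzero(wanted[loc] == words)
            for pos in candidate_pos:
                pos = int(pos)
                for idx in seed_to_patterns[int(words[pos])]:
                    pat, owner, strand = patterns[idx]
                    if text[pos : pos + len(pat)] == pat:
                        five_prime = pos if strand == "+" else pos + len(pat) - 1
                        occurrences[owner].append(AlignmentHit(name, five_prime, strand))
        for s in long_reads:
            hits = occurrences.get(s, [])
            if len(hits) == 1:
                results[s] = (hits[0], "ok")
            else:
                results[s] = (None, UNMAPPED if not hits else MULTI_MAPPED)
        return results
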