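"""Barcode demultiplexing and read trimming.

Splinkerette reads start with a 6 nt multiplexing barcode drawn from the
{A,G,T} alphabet (IUPAC D — the missing C keeps the barcode distinct from
the Csp6I half site), followed by one base left over from ligation, then
genomic sequence.  Demultiplexing assigns each read to the unique barcode
matching its first six bases within ``max_mismatch`` (default 0: the
barcodes have no designed pairwise-distance guarantee, so mismatch
tolerance is opt-in).  Trimming removes the barcode plus ligation base,
strips any 3' library adapter by exact suffix-prefix overlap of at least
5 nt, and retains reads of 7 bp or longer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import pandas as pd

BARCODE_ALPHABET = set("AGT")

#: trim discard reason codes
TOO_SHORT_PRETRIM = "too_short_pretrim"
TOO_SHORT_POSTTRIM = "too_short_posttrim"

UNMATCHED = "unmatched"


@dataclass(frozen=True)
class TrimmedRead:
    sample_id: str
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class SampleSheet:
    """Validated barcode -> sample mapping."""

    def __init__(self, entries: Mapping[str, str], barcode_length: int = 6):
        for barcode in entries:
            if len(barcode) != barcode_length:
                raise ValueError(f"barcode {barcode!r} is not {barcode_length} nt")
            if set(barcode) - BARCODE_ALPHABET:
                raise ValueError(
                    f"barcode {barcode!r} uses bases outside {{A,G,T}} (IUPAC D)"
                )
        if len(set(entries)) != len(entries):
            raise ValueError("duplicate barcodes in sample sheet")
        self.entries: Dict[str, str] = dict(entries)
        self.barcode_length = barcode_length

    @classmethod
    def from_tsv(cls, path: str | Path, barcode_length: int = 6) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t")
        barcodes = [str(b) for b in frame["barcode"]]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in sample sheet")
        return cls(dict(zip(barcodes, frame["sample_id"].astype(str))), barcode_length)

    def __len__(self) -> int:
        return len(self.entries)


def _iter_fastq(source) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ path or pass through
    an iterable of such tuples."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.FastxFile(str(source)) as fh:
            for entry in fh:
                yield entry.name, entry.sequence, entry.quality or ""
    else:
        yield from source


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    source,
    sheet: SampleSheet,
    max_mismatch: int = 0,
) -> Tuple[Dict[str, List[Tuple[str, str, str]]], List[Tuple[str, str, str]], pd.DataFrame]:
    """Split a FASTQ stream by barcode.

    A read is assigned when exactly one barcode matches its first
    ``barcode_length`` bases within ``max_mismatch``; reads matching zero
    or several barcodes land in the unmatched bin.  Returns per-sample
    record lists, the unmatched bin, and a tally frame whose counts sum to
    the input read count.
    """
    if not sheet.entries:
        raise ValueError("sample sheet is empty")
    n = sheet.barcode_length
    by_sample: Dict[str, List[Tuple[str, str, str]]] = {
        s: [] for s in sheet.entries.values()
    }
    unmatched: List[Tuple[str, str, str]] = []
    exact = sheet.entries

    for record in _iter_fastq(source):
        prefix = record[1][:n]
        if max_mismatch == 0:
            sample = exact.get(prefix)
        else:
            candidates = [
                s for b, s in exact.items()
                if len(prefix) == n and _hamming(prefix, b) <= max_mismatch
            ]
            sample = candidates[0] if len(candidates) == 1 else None
        if sample is None:
            unmatched.append(record)
        else:
            by_sample[sample].append(record)

    tallies = pd.DataFrame(
        [(s, len(reads)) for s, reads in by_sample.items()]
        + [(UNMATCHED, len(unmatched))],
        columns=["sample_id", "assigned"],
    )
    return by_sample, unmatched, tallies


def _adapter_cut(seq: str, adapter: str, min_overlap: int) -> int:
    """Offset at which the longest read suffix equal to an adapter prefix
    (length >= min_overlap) begins, or len(seq) when there is none."""
    if not adapter:
        return len(seq)
    probe = adapter[:min_overlap]
    longest = min(len(seq), len(adapter))
    start = len(seq) - longest
    i = seq.find(probe, start)
    while i != -1:
        k = len(seq) - i
        if k >= min_overlap and seq[i:] == adapter[:k]:
            return i
        i = seq.find(probe, i + 1)
    return len(seq)


def trim(
    seq: str,
    barcode_length: int = 6,
    ligation_bases: int = 1,
    adapter: Optional[str] = None,
    min_length: int = 7,
    min_overlap: int = 5,
) -> Tuple[Optional[str], str]:
    """Trim one assigned read to its genomic portion.

    Removes the first ``barcode_length + ligation_bases`` bases, then the
    longest 3' suffix exactly matching a prefix of ``adapter`` (overlap of
    at least ``min_overlap``).  Returns ``(genomic_sequence, "ok")`` when
    at least ``min_length`` bases remain, else ``(None, reason)``.
    """
    head = barcode_length + ligation_bases
    if len(seq) < head:
        return None, TOO_SHORT_PRETRIM
    body = seq[head:]
    if adapter:
        body = body[: _adapter_cut(body, adapter, min_overlap)]
    if len(body) < min_length:
        return None, TOO_SHORT_POSTTRIM
    return body, "ok"


def trim_sample(
    records: Iterable[Tuple[str, str, str]],
    sample_id: str,
    barcode_length: int = 6,
    ligation_bases: int = 1,
    adapter: Optional[str] = None,
    min_length: int = 7,
    min_overlap: int = 5,
) -> Tuple[List[TrimmedRead], Dict[str, int]]:
    """Trim every record of one sample; returns retained reads and a
    per-reason discard tally (retained + discarded = assigned)."""
    kept: List[TrimmedRead] = []
    discarded: Dict[str, int] = {TOO_SHORT_PRETRIM: 0, TOO_SHORT_POSTTRIM: 0}
    for read_id, seq, _ in records:
        body, reason = trim(
            seq, barcode_length, ligation_bases, adapter, min_length, min_overlap
        )
        if body is None:
            discarded[reason] += 1
        else:
            kept.append(TrimmedRead(sample_id, read_id, body))
    return kept, discarded


def write_fastq(records: Iterable[Tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for read_id, seq, qual in records:
            out.write(f"@{read_id}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


def demux_report(
    tallies: pd.DataFrame, discards: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Combine demultiplex tallies and trim discard counts into the demux
    report table (sample, assigned, retained, discarded_by_reason)."""
    rows = []
    for row in tallies.itertuples(index=False):
        d = discards.get(row.sample_id, {})
        lost = sum(d.values())
        rows.append(
            (
                row.sample_id,
                row.assigned,
                row.assigned - lost if row.sample_id != UNMATCHED else 0,
                d.get(TOO_SHORT_PRETRIM, 0),
                d.get(TOO_SHORT_POSTTRIM, 0),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "assigned", "retained",
                 TOO_SHORT_PRETRIM, TOO_SHORT_POSTTRIM],
    )
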