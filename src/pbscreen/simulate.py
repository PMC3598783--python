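"""Synthetic activation-tagging screen generator.

This module fabricates everything the analysis pipeline consumes, with
known ground truth: a random genome with annotated genes, a library of
mutagenised clones carrying 1-11 piggyBac insertions at TTAA sites (mean
~6, balanced orientation), a drug-selection step that keeps clones with a
sense-orientation insertion within an activation window upstream of a
designated resistance gene, and barcoded splinkerette FASTQ reads whose 5'
ends sit exactly at Csp6I cut coordinates.

Read structure mirrors the splinkerette template: a 6 nt barcode over the
{A,G,T} alphabet, one ligation base left from the Csp6I half site (fixed to
"T", the first base of the TA overhang), then genomic sequence starting at
the cut and reading toward the insertion.  In the noise-free default every
read carries a full-length alignable genomic portion; with
``clip_at_junction`` enabled the read instead stops at the transposon
junction and runs into library adapter sequence, which downstream trimming
must remove.  Per-site depths are bi-phasic: true insertion sites draw from
a log-normal capped below at 100 reads, while background sites
(mis-ligation and carry-over artefacts) draw from a Poisson truncated to
[1, 50].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, SyntheticGenome, revcomp, TTAA, CSP6I_MOTIF
from .sitecall import cut_coordinate

#: single base retained from ligation at the Csp6I half site (trimmed away
#: with the barcode, so any fixed choice round-trips)
LIGATION_BASE = "T"

#: library adapter sequence that appears at the 3' end of reads whose
#: restriction fragment is shorter than the read length
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BARCODE_ALPHABET = "AGT"  # IUPAC D: the linker barcodes carry no C

# deterministic per-operation seed tags so one SimConfig.seed drives
# independent streams for genome, library, selection sampling and reads
_SEED_GENOME, _SEED_LIBRARY, _SEED_READS, _SEED_SHEET = 11, 13, 17, 19


@dataclass
class SimConfig:
    """Parameters of a synthetic screen.

    Defaults encode the screen conditions the pipeline is designed around:
    ~10^4 clones carrying a truncated-Poisson(6) number of insertions on
    [1, 11], balanced orientations, a 64 kb activation window, signal depth
    of at least 100 reads per true site (log-normal, median 300), and 10^3
    background sites with Poisson(5) counts truncated to [1, 50].
    """

    seed: int = 0
    n_clones: int = 10_000
    insertions_min: int = 1
    insertions_max: int = 11
    insertions_mean: float = 6.0
    orientation_balance: float = 0.5
    activation_window_kb: float = 64.0
    signal_depth_median: float = 300.0
    signal_depth_sigma: float = 0.5
    signal_depth_min: int = 100
    background_mean: float = 5.0
    background_upper: int = 50
    n_background_sites: int = 1_000
    barcode_length: int = 6
    read_length: int = 50
    substitution_rate: float = 0.0
    # when True, reads stop at the transposon junction and run into library
    # adapter (read-through realism); when False (noise-free default) the
    # genomic portion continues at full read length past the junction, so
    # every emitted read carries a fully alignable genomic sequence
    clip_at_junction: bool = False
    # genome geometry
    genome_length: int = 5_000_000
    n_genes: int = 12
    gene_length: int = 20_000
    chromosome_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length < 100_000:
            raise ValueError("requested genome length must be >= 100 kb")
        for name in ("n_clones", "insertions_min", "insertions_max", "n_genes",
                     "gene_length", "barcode_length", "read_length",
                     "n_background_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.orientation_balance <= 1.0:
            raise ValueError("orientation_balance must lie in [0, 1]")
        if self.insertions_min > self.insertions_max:
            raise ValueError("insertions_min must not exceed insertions_max")
        if self.signal_depth_min <= 0 or self.background_mean <= 0:
            raise ValueError("depth parameters must be positive")

    @property
    def activation_window(self) -> int:
        return int(round(self.activation_window_kb * 1000))

    @property
    def genomic_read_length(self) -> int:
        return self.read_length - self.barcode_length - 1


@dataclass(frozen=True)
class CloneGenotype:
    """One mutagenised founder cell: its set of transposon insertions as
    ``(chromosome, ttaa_coordinate, orientation)`` with orientation the
    reference strand (+/-) the transposon's promoter points along."""

    clone_id: str
    insertions: FrozenSet[Tuple[str, int, str]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.insertions) <= 11:
            raise ValueError("a clone carries between 1 and 11 insertions")


@dataclass(frozen=True)
class SelectionRule:
    """Survival rule of a drug screen.

    A clone survives when it carries at least one insertion in sense
    orientation (matching the driver gene's strand) within
    ``window_kb`` upstream of the driver's first coding base.  When
    ``modifier_gene`` is set, survival additionally requires any insertion
    inside the modifier's gene body (the cooperative scenario).
    """

    driver_gene: str
    window_kb: float = 64.0
    modifier_gene: Optional[str] = None


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([tag, config.seed])


# --- genome ----------------------------------------------------------------

def make_genome(config: SimConfig) -> Tuple[SyntheticGenome, List[GeneAnnotation]]:
    """Generate a uniform-random genome and place non-overlapping genes.

    Genes are laid out one per equal-width slot so that each gene's full
    upstream activation window (and the 25 kb assignment margin) stays clear
    of its neighbours'.  Gene 0 is the resistance driver and gene 1 the
    modifier of cooperative scenarios; the rest are passengers.  Every
    gene is guaranteed at least one TTAA and one GTAC in its activation
    window (motifs are injected in the vanishingly rare case the random
    sequence lacks one), and the motif indices are rebuilt by rescanning
    the final sequence.
    """
    rng = _rng(config, _SEED_GENOME)
    window = config.activation_window
    margin = 25_000
    slot = config.genome_length // config.n_genes
    need = window + config.gene_length + 2 * margin
    if slot < need:
        raise ValueError(
            f"genome of {config.genome_length} bp cannot hold {config.n_genes} genes "
            f"with non-overlapping {config.activation_window_kb:g} kb upstream windows "
            f"(need >= {need} bp per gene)"
        )

    seq = rng.integers(0, 4, size=config.genome_length)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = bases[seq]

    genes: List[GeneAnnotation] = []
    roles = ["resistance_driver", "modifier"] + ["passenger"] * (config.n_genes - 2)
    for i in range(config.n_genes):
        lo, hi = i * slot, (i + 1) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start = int(rng.integers(lo + margin + window, hi - margin - config.gene_length))
            end = start + config.gene_length
            cds = start
            win_lo, win_hi = start - window, start
        else:
            end = int(rng.integers(lo + margin + config.gene_length, hi - margin - window))
            start = end - config.gene_length
            cds = end - 1
            win_lo, win_hi = end, end + window
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{i:03d}",
                chromosome=config.chromosome_name,
                strand=strand,
                start=start,
                end=end,
                cds_start=cds,
                role=roles[i] if i < len(roles) else "passenger",
            )
        )
        # guarantee both motifs inside the activation window
        for motif in (TTAA, CSP6I_MOTIF):
            window_text = arr[win_lo:win_hi].tobytes().decode("ascii")
            if motif not in window_text:
                pos = int(rng.integers(win_lo, win_hi - 4))
                arr[pos : pos + 4] = np.frombuffer(motif.encode(), dtype=np.uint8)

    genome = SyntheticGenome.from_sequences(
        {config.chromosome_name: arr.tobytes().decode("ascii")}
    )
    return genome, genes


# --- clone library ---------------------------------------------------------

def truncated_poisson_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """Probability mass of Poisson(mean) renormalised on {lo..hi}."""
    k = np.arange(lo, hi + 1)
    p = stats.poisson.pmf(k, mean)
    return p / p.sum()


def make_library(genome: SyntheticGenome, config: SimConfig) -> List[CloneGenotype]:
    """Draw the mutagenised clone library.

    Insertion counts follow Poisson(``insertions_mean``) truncated to
    [``insertions_min``, ``insertions_max``]; positions are uniform over
    the genome's TTAA sites without replacement within a clone;
    orientations are Bernoulli(``orientation_balance``) toward ``+``.
    """
    rng = _rng(config, _SEED_LIBRARY)
    sites: List[Tuple[str, int]] = [
        (chrom, int(pos))
        for chrom, index in genome.ttaa_index.items()
        for pos in index
    ]
    if not sites:
        raise ValueError("genome has no TTAA sites")
    ks = np.arange(config.insertions_min, config.insertions_max + 1)
    pmf = truncated_poisson_pmf(config.insertions_mean, config.insertions_min,
                                config.insertions_max)
    counts = rng.choice(ks, size=config.n_clones, p=pmf)
    clones: List[CloneGenotype] = []
    n_sites = len(sites)
    for ci, k in enumerate(counts):
        idx = rng.choice(n_sites, size=int(k), replace=False)
        orient = rng.random(int(k)) < config.orientation_balance
        ins = frozenset(
            (sites[j][0], sites[j][1], "+" if o else "-")
            for j, o in zip(idx, orient)
        )
        clones.append(CloneGenotype(clone_id=f"clone{ci:05d}", insertions=ins))
    return clones


# --- selection -------------------------------------------------------------

def _upstream_window(gene: GeneAnnotation, window: int) -> Tuple[int, int]:
    """Half-open genomic interval of coordinates whose distance upstream of
    the first coding base is in (0, window]."""
    if gene.strand == "+":
        return gene.cds_start - window, gene.cds_start
    return gene.cds_start + 1, gene.cds_start + window + 1

def _activates(ins: Tuple[str, int, str], gene: GeneAnnotation, window: int) -> bool:
    chrom, pos, orient = ins
    if chrom != gene.chromosome or orient != gene.strand:
        return False
    lo, hi = _upstream_window(gene, window)
    return lo <= pos < hi


def _intragenic(ins: Tuple[str, int, str], gene: GeneAnnotation) -> bool:
    chrom, pos, _ = ins
    return chrom == gene.chromosome and gene.start <= pos < gene.end


def apply_selection(
    library: Sequence[CloneGenotype],
    genes: Sequence[GeneAnnotation],
    rule: SelectionRule,
) -> Tuple[List[CloneGenotype], pd.DataFrame]:
    """Apply a drug-selection rule to the library.

    Returns the surviving clones and a truth table recording, per clone,
    whether it survived and which insertions caused the survival.
    """
    by_id = {g.gene_id: g for g in genes}
    try:
        driver = by_id[rule.driver_gene]
    except KeyError:
        raise KeyError(f"unknown driver gene {rule.driver_gene!r}") from None
    modifier = None
    if rule.modifier_gene is not None:
        try:
            modifier = by_id[rule.modifier_gene]
        except KeyError:
            raise KeyError(f"unknown modifier gene {rule.modifier_gene!r}") from None
    window = int(round(rule.window_kb * 1000))

    survivors: List[CloneGenotype] = []
    rows = []
    for clone in library:
        causal = [ins for ins in clone.insertions if _activates(ins, driver, window)]
        ok = bool(causal)
        if ok and modifier is not None:
            modifier_hits = [ins for ins in clone.insertions if _intragenic(ins, modifier)]
            ok = bool(modifier_hits)
            causal = causal + modifier_hits if ok else []
        if ok:
            survivors.append(clone)
        rows.append(
            (
                clone.clone_id,
                ok,
                ";".join(f"{c}:{p}:{o}" for c, p, o in sorted(causal)),
            )
        )
    truth = pd.DataFrame(rows, columns=["clone_id", "survived", "causal_insertions"])
    return survivors, truth


# --- sample sheets ---------------------------------------------------------

def make_sample_sheet(
    sample_ids: Sequence[str], config: SimConfig
) -> Dict[str, str]:
    """Draw distinct 6 nt barcodes over {A,G,T} for the given samples."""
    rng = _rng(config, _SEED_SHEET)
    sheet: Dict[str, str] = {}
    used = set()
    for sample in sample_ids:
        while True:
            code = "".join(
                _BARCODE_ALPHABET[i]
                for i in rng.integers(0, len(_BARCODE_ALPHABET), config.barcode_length)
            )
            if code not in used:
                used.add(code)
                sheet[code] = sample
                break
    return sheet


def write_sample_sheet(sheet: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"barcode": list(sheet.keys()), "sample_id": list(sheet.values())}
    ).to_csv(path, sep="\t", index=False)


# --- read simulation -------------------------------------------------------

def _primer_side_site(
    ttaa: int, orient: str, csp6i: np.ndarray
) -> Optional[Tuple[int, str]]:
    """Csp6I motif anchoring the splinkerette read of one insertion.

    A sense (+) insertion is read from the plus strand: the nearest motif
    fully 5' of the TTAA, reading rightward toward the junction.  An
    antisense (-) insertion is read from the minus strand: the nearest
    motif fully 3' of the TTAA, reading leftward.  Returns
    ``(gtac_start, read_strand)`` or ``None`` when no motif flanks the
    insertion on the primer side.
    """
    if orient == "+":
        i = int(np.searchsorted(csp6i, ttaa - 4, side="right")) - 1
        if i < 0:
            return None
        return int(csp6i[i]), "+"
    i = int(np.searchsorted(csp6i, ttaa + 4, side="left"))
    if i >= len(csp6i):
        return None
    return int(csp6i[i]), "-"


def _signal_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal depths truncated below at ``signal_depth_min`` by
    resampling."""
    mu = math.log(config.signal_depth_median)
    out = np.rint(rng.lognormal(mu, config.signal_depth_sigma, size=n)).astype(int)
    bad = out < config.signal_depth_min
    while bad.any():
        out[bad] = np.rint(
            rng.lognormal(mu, config.signal_depth_sigma, size=int(bad.sum()))
        ).astype(int)
        bad = out < config.signal_depth_min
    return out


def truncated_poisson_counts(
    mean: float, lo: int, hi: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(mean) draws truncated to [lo, hi] by resampling."""
    out = rng.poisson(mean, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


SIDECAR_COLUMNS = [
    "sample_id", "chromosome", "csp6i_coordinate", "read_strand", "cut",
    "ttaa_coordinate", "fragment_length", "count", "origin", "clone_ids", "status",
]


def _read_sequence(
    chrom_seq: str,
    gtac: int,
    strand: str,
    barcode: str,
    config: SimConfig,
    junction: Optional[int],
    adapter: str,
) -> str:
    """Assemble one read: barcode + ligation base + genomic portion from
    the cut toward the insertion junction, adapter-filled to full length."""
    cut = cut_coordinate(gtac, strand)
    n = config.genomic_read_length
    if strand == "+":
        stop = len(chrom_seq) if junction is None else min(junction + 4, len(chrom_seq))
        gseq = chrom_seq[cut : min(cut + n, stop)]
    else:
        start = 0 if junction is None else max(junction, 0)
        gseq = revcomp(chrom_seq[max(cut - n + 1, start) : cut + 1])
    fill = adapter[: n - len(gseq)]
    while len(gseq) + len(fill) < n:  # fragment shorter than adapter coverage
        fill = fill + adapter[: n - len(gseq) - len(fill)]
    return barcode + LIGATION_BASE + gseq + fill


def simulate_reads(
    clones_by_sample: Mapping[str, Sequence[CloneGenotype]],
    genome: SyntheticGenome,
    sheet: Mapping[str, str],
    config: SimConfig,
    fastq_path: str | Path,
    adapter: str = DEFAULT_ADAPTER,
) -> pd.DataFrame:
    """Emit multiplexed splinkerette FASTQ reads plus a truth sidecar.

    Every insertion of every clone in a sample yields reads whose genomic
    portion starts exactly at the primer-side Csp6I cut; insertions with no
    motif on the primer side are recorded in the sidecar with status
    ``no_csp6i`` and zero reads.  Background sites are random Csp6I cuts
    with truncated-Poisson counts.  Base qualities are constant ("I").
    The sidecar lists every emitted site with its origin and read count;
    FASTQ and sidecar are exactly consistent by construction.
    """
    rng = _rng(config, _SEED_READS)
    barcode_of = {sample: bc for bc, sample in sheet.items()}
    missing = [s for s in clones_by_sample if s not in barcode_of]
    if missing:
        raise KeyError(f"samples missing from sheet: {missing}")

    rows = []
    fastq_path = Path(fastq_path)
    with open(fastq_path, "w") as out:
        for sample, clones in clones_by_sample.items():
            barcode = barcode_of[sample]
            # aggregate per site: several clones can share one site
            site_info: Dict[Tuple[str, int, str], Dict] = {}
            undetectable = []
            for clone in clones:
                for chrom, ttaa, orient in sorted(clone.insertions):
                    anchored = _primer_side_site(
                        ttaa, orient, genome.csp6i_index[chrom]
                    )
                    if anchored is None:
                        undetectable.append((clone.clone_id, chrom, ttaa, orient))
                        continue
                    gtac, strand = anchored
                    key = (chrom, gtac, strand)
                    info = site_info.setdefault(
                        key, {"ttaa": ttaa, "clones": [], "n_events": 0}
                    )
                    info["clones"].append(clone.clone_id)
                    info["n_events"] += 1

            keys = sorted(site_info)
            depths_per_event = {
                key: _signal_depths(site_info[key]["n_events"], config, rng)
                for key in keys
            }

            # background: random cut sites not already used as signal
            bg_keys: List[Tuple[str, int, str]] = []
            chroms = sorted(genome.csp6i_index)
            n_all = {c: len(genome.csp6i_index[c]) for c in chroms}
            total = sum(n_all.values())
            attempts = 0
            while len(bg_keys) < config.n_background_sites and attempts < 20:
                attempts += 1
                need = config.n_background_sites - len(bg_keys)
                flat = rng.integers(0, total, size=need)
                strands = np.where(rng.random(need) < 0.5, "+", "-")
                for f, st in zip(flat, strands):
                    offset = int(f)
                    for c in chroms:
                        if offset < n_all[c]:
                            key = (c, int(genome.csp6i_index[c][offset]), str(st))
                            if key not in site_info and key not in set(bg_keys):
                                bg_keys.append(key)
                            break
                        offset -= n_all[c]
            bg_counts = truncated_poisson_counts(
                config.background_mean, 1, config.background_upper,
                len(bg_keys), rng,
            )

            emit: List[Tuple[Tuple[str, int, str], int, Optional[int], str, str]] = []
            for key in keys:
                info = site_info[key]
                emit.append(
                    (key, int(depths_per_event[key].sum()), info["ttaa"],
                     "signal", ";".join(info["clones"]))
                )
            for key, n in zip(bg_keys, bg_counts):
                emit.append((key, int(n), None, "background", ""))

            for key, depth, ttaa, origin, clone_ids in emit:
                chrom, gtac, strand = key
                junction = ttaa if config.clip_at_junction else None
                seq = _read_sequence(
                    genome.chromosomes[chrom], gtac, strand, barcode, config,
                    junction, adapter,
                )
                if config.substitution_rate > 0:
                    records = [
                        _mutate(seq, config.substitution_rate, rng)
                        for _ in range(depth)
                    ]
                else:
                    records = [seq] * depth
                qual = "I" * config.read_length
                chunk = []
                for i, s in enumerate(records):
                    chunk.append(
                        f"@{sample}|{chrom}|{gtac}|{strand}|{i}\n{s}\n+\n{qual}\n"
                    )
                out.write("".join(chunk))
                cut = cut_coordinate(gtac, strand)
                if ttaa is None:
                    frag = -1  # background fragments are unbounded here
                elif strand == "+":
                    frag = (ttaa + 4) - cut
                else:
                    frag = cut - ttaa + 1
                rows.append(
                    (sample, chrom, gtac, strand, cut, -1 if ttaa is None else ttaa,
                     frag, depth, origin, clone_ids, "ok")
                )
            for clone_id, chrom, ttaa, orient in undetectable:
                rows.append(
                    (sample, chrom, -1, orient, -1, ttaa, 0, 0, "signal",
                     clone_id, "no_csp6i")
                )
    sidecar = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    return sidecar


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if not len(hits):
        return seq
    out = list(seq)
    for i in hits:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def annotate_detectability(
    sidecar: pd.DataFrame,
    genome: SyntheticGenome,
    config: SimConfig,
    adapter: str = DEFAULT_ADAPTER,
) -> pd.DataFrame:
    """Add a ``detectable`` column to a truth sidecar.

    A site is detectable when the read it emits, after barcode/ligation
    trimming and adapter removal, is at least 7 bases long, aligns uniquely
    across both genome strands, and anchors back to its cut coordinate.
    Short restriction fragments can fail any of these (adapter remnants
    shorter than the 5-base removal floor, sub-7 bp genomic portions, or
    non-unique short sequences), which is exactly the dropout a real screen
    suffers for insertions very close to a Csp6I site.
    """
    from .align import ExactAligner
    from .demux import trim

    ok = sidecar["status"] == "ok"
    seqs = {}
    for row in sidecar[ok].itertuples(index=False):
        junction = None
        if config.clip_at_junction and row.ttaa_coordinate >= 0:
            junction = int(row.ttaa_coordinate)
        seq = _read_sequence(
            genome.chromosomes[row.chromosome], int(row.csp6i_coordinate),
            row.read_strand, "N" * config.barcode_length, config, junction, adapter,
        )
        trimmed, reason = trim(
            seq, barcode_length=config.barcode_length, ligation_bases=1,
            adapter=adapter,
        )
        seqs[(row.sample_id, row.chromosome, row.csp6i_coordinate, row.read_strand)] = trimmed
    aligner = ExactAligner(genome)
    mapped = aligner.map_unique([s for s in seqs.values() if s is not None])
    detectable = []
    for row in sidecar.itertuples(index=False):
        if row.status != "ok":
            detectable.append(False)
            continue
        trimmed = seqs[(row.sample_id, row.chromosome, row.csp6i_coordinate, row.read_strand)]
        if trimmed is None:
            detectable.append(False)
            continue
        hit, _ = mapped[trimmed]
        detectable.append(
            hit is not None
            and hit.chromosome == row.chromosome
            and hit.strand == row.read_strand
            and hit.five_prime_coordinate == row.cut
        )
    out = sidecar.copy()
    out["detectable"] = detectable
    return out
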