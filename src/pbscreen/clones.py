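"""Clonal deconvolution of resistant colonies.

Each drug-resistant colony descends from a single mutagenised founder cell,
so colonies sharing (essentially) the same set of insertion sites were
seeded by the same founder clone.  This module formalises the clustering:
per-colony site fractions are filtered (sites below 1% of the colony's
reads removed, then the top 1-10 by frequency kept, matching the expected
number of insertions per cell), colonies that look like mixtures of two or
more otherwise-unrelated colony groups are excluded, and the remainder are
single-linkage clustered on Jaccard similarity of their retained site sets.

Once founder signatures are annotated to genes, the co-occurrence
classifier separates genes able to drive resistance alone (some founder
carries them with no other annotated gene) from candidate modifiers that
only ever appear alongside a specific driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import pandas as pd

SiteKey = Tuple[str, int, str]


@dataclass(frozen=True)
class ColonyProfile:
    """Filtered site profile of one resistant colony: retained site keys
    and each retained site's fraction of the colony's total reads."""

    colony_id: str
    site_fractions: Mapping[SiteKey, float]
    retained_sites: FrozenSet[SiteKey]


@dataclass(frozen=True)
class FounderClone:
    """A cluster of colonies sharing one insertion signature."""

    founder_id: str
    signature: FrozenSet[SiteKey]
    member_colonies: FrozenSet[str]


def colony_profile(
    counts: Mapping[SiteKey, int],
    colony_id: str,
    min_fraction: float = 0.01,
    max_sites: int = 10,
) -> ColonyProfile:
    """Build the filtered site profile of one colony.

    Fractions are computed over the colony's total reads; sites strictly
    below ``min_fraction`` are removed; of the remainder the ``max_sites``
    highest-fraction sites are retained, ties breaking toward the smaller
    site coordinate.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError(f"colony {colony_id!r} has no reads")
    fractions = {k: v / total for k, v in counts.items()}
    kept = [(k, f) for k, f in fractions.items() if f >= min_fraction]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    kept = kept[:max_sites]
    return ColonyProfile(
        colony_id=colony_id,
        site_fractions={k: f for k, f in kept},
        retained_sites=frozenset(k for k, _ in kept),
    )


def jaccard(a: FrozenSet, b: FrozenSet) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _link_clusters(
    profiles: Sequence[ColonyProfile], jaccard_min: float
) -> List[List[ColonyProfile]]:
    """Single-linkage connected components under Jaccard >= jaccard_min."""
    parent = list(range(len(profiles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if jaccard(profiles[i].retained_sites, profiles[j].retained_sites) >= jaccard_min:
                parent[find(i)] = find(j)
    groups: Dict[int, List[ColonyProfile]] = {}
    for i, p in enumerate(profiles):
        groups.setdefault(find(i), []).append(p)
    return list(groups.values())


def flag_multiclone(
    profiles: Sequence[ColonyProfile],
    jaccard_min: float = 0.5,
    slack: int = 1,
) -> Set[str]:
    """Identify colonies that look like mixtures of several founders.

    A colony is flagged when, after clustering the *other* colonies, its
    retained set is a strict superset of the signatures of two or more
    distinct clusters (each signature contained up to ``slack`` missing
    sites) and is fully explained by the union of those signatures.  A
    colony whose retained set exactly equals another colony's set is never
    flagged: the duplicate links the would-be component groups into one
    cluster, leaving no multi-component structure to detect.
    """
    flagged: Set[str] = set()
    for idx, colony in enumerate(profiles):
        others = [p for i, p in enumerate(profiles) if i != idx]
        if not others:
            continue
        components = []
        for group in _link_clusters(others, jaccard_min):
            signature = frozenset().union(*(p.retained_sites for p in group))
            missing = len(signature - colony.retained_sites)
            strict_superset = len(colony.retained_sites - signature) >= 1
            if missing <= slack and strict_superset and signature:
                components.append(signature)
        if len(components) < 2:
            continue
        union: FrozenSet[SiteKey] = frozenset().union(*components)
        if colony.retained_sites <= union:
            flagged.add(colony.colony_id)
    return flagged


def cluster_colonies(
    profiles: Sequence[ColonyProfile],
    jaccard_min: float = 0.5,
) -> List[FounderClone]:
    """Single-linkage clustering of colonies into founder clones.

    Each cluster's signature is the union of member retained sets, so a
    site dropped by sampling in one colony is still kept.  Output order is
    deterministic and permutation-invariant: clusters sort by their
    smallest member site key.
    """
    clusters = _link_clusters(list(profiles), jaccard_min)
    founders = []
    for group in clusters:
        signature = frozenset().union(*(p.retained_sites for p in group))
        founders.append(
            (
                min(signature),
                signature,
                frozenset(p.colony_id for p in group),
            )
        )
    founders.sort(key=lambda t: t[0])
    return [
        FounderClone(founder_id=f"founder{i:03d}", signature=sig, member_colonies=members)
        for i, (_, sig, members) in enumerate(founders)
    ]


def co_occurrence(
    founder_genes: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Classify genes as standalone drivers or co-occurring modifiers.

    ``founder_genes`` maps founder id -> set of annotated gene ids in its
    signature.  A gene is a ``standalone_driver`` when some founder carries
    it and no other gene.  A gene is a ``co_occurring_modifier`` (relative
    to a driver) when it appears in at least one founder, never alone, and
    every founder carrying it also carries the driver.  Everything else is
    ``unclassified``.  Supporting founder ids are recorded per gene.
    """
    genes: Set[str] = set()
    for gs in founder_genes.values():
        genes |= gs
    rows = []
    for gene in sorted(genes):
        carriers = {f for f, gs in founder_genes.items() if gene in gs}
        alone = any(founder_genes[f] == {gene} for f in carriers)
        if alone:
            rows.append((gene, "standalone_driver", "", ";".join(sorted(carriers))))
            continue
        partners = [
            d
            for d in sorted(genes - {gene})
            if all(d in founder_genes[f] for f in carriers)
        ]
        if carriers and partners:
            rows.append(
                (gene, "co_occurring_modifier", ";".join(partners),
                 ";".join(sorted(carriers)))
            )
        else:
            rows.append((gene, "unclassified", "", ";".join(sorted(carriers))))
    return pd.DataFrame(
        rows, columns=["gene_id", "classification", "drivers", "founders"]
    )


def fraction_matrix(profiles: Sequence[ColonyProfile]) -> pd.DataFrame:
    """Colony-by-site fraction matrix (heat-map-ready)."""
    sites = sorted({k for p in profiles for k in p.retained_sites})
    data = {
        p.colony_id: [p.site_fractions.get(s, 0.0) for s in sites] for p in profiles
    }
    index = [f"{c}:{pos}:{strand}" for c, pos, strand in sites]
    return pd.DataFrame(data, index=index)
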