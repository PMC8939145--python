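"""Guilt-by-association statistics over anchor directons.

For every non-anchor protein family (cluster of homologs) found in the
directon of an anchor gene, the raw occurrence count and a
redundancy-weighted frequency are computed.  Redundancy weighting counters
the over-representation of near-identical loci in genome collections: each
locus weighs 1/n where n is the size of its anchor's tier-1 (90% identity)
cluster, so a family's weighted frequency is its fraction of independent
(non-redundant) observations.  Families present in more than ``min_loci``
loci and at least ``min_wfreq`` of the independent observations are
flagged as non-randomly associated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

DEFAULT_MIN_LOCI = 20
DEFAULT_MIN_WEIGHTED_FREQUENCY = 0.01


@dataclass(frozen=True)
class LocusWeight:
    locus_id: str
    redundancy_group: int
    weight: float


def compute_locus_weights(
    anchor_redundancy_group: Mapping[str, int]
) -> list[LocusWeight]:
    """Weights 1/n per redundancy group of the anchor protein.

    ``anchor_redundancy_group`` maps locus id -> tier-1 cluster id of the
    locus anchor.  Weights within a group sum to 1, so the total weight
    equals the number of distinct anchor groups.
    """
    sizes: dict[int, int] = {}
    for group in anchor_redundancy_group.values():
        sizes[group] = sizes.get(group, 0) + 1
    return [
        LocusWeight(locus_id=lid, redundancy_group=group, weight=1.0 / sizes[group])
        for lid, group in sorted(anchor_redundancy_group.items())
    ]


@dataclass(frozen=True)
class AssociationRecord:
    family_cluster_id: int
    raw_count: int
    weighted_frequency: float
    passes_threshold: bool = False


def weighted_association(
    directon_families: Mapping[str, Iterable[int]],
    weights: Iterable[LocusWeight],
) -> list[AssociationRecord]:
    """Raw counts and weighted frequencies of families in anchor directons.

    ``directon_families`` maps locus id -> family cluster ids present in
    that locus's anchor directon (the anchor's own family excluded by the
    caller).  A family counts at most once per locus.  The weighted
    frequency is the weight sum of the loci containing the family divided
    by the total locus weight.
    """
    weight_of = {w.locus_id: w.weight for w in weights}
    missing = set(directon_families) - set(weight_of)
    if missing:
        raise ValueError(f"loci without weights: {sorted(missing)[:5]}")
    total = sum(weight_of[lid] for lid in directon_families)
    counts: dict[int, int] = {}
    wsums: dict[int, float] = {}
    for lid, families in directon_families.items():
        for fam in set(families):
            counts[fam] = counts.get(fam, 0) + 1
            wsums[fam] = wsums.get(fam, 0.0) + weight_of[lid]
    return [
        AssociationRecord(
            family_cluster_id=fam,
            raw_count=counts[fam],
            weighted_frequency=(wsums[fam] / total) if total > 0 else 0.0,
        )
        for fam in sorted(counts)
    ]


def filter_associations(
    records: Iterable[AssociationRecord],
    min_loci: int = DEFAULT_MIN_LOCI,
    min_wfreq: float = DEFAULT_MIN_WEIGHTED_FREQUENCY,
) -> list[AssociationRecord]:
    """Keep families with raw_count > min_loci and weighted frequency >=
    min_wfreq, sorted by weighted frequency descending."""
    kept = [
        AssociationRecord(
            family_cluster_id=r.family_cluster_id,
            raw_count=r.raw_count,
            weighted_frequency=r.weighted_frequency,
            passes_threshold=True,
        )
        for r in records
        if r.raw_count > min_loci and r.weighted_frequency >= min_wfreq
    ]
    kept.sort(key=lambda r: (-r.weighted_frequency, r.family_cluster_id))
    return kept
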