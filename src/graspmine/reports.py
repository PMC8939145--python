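"""End-to-end mining runs and deterministic report bundles.

``run_mine`` composes the pipeline: anchor neighborhoods -> homolog
clustering of every neighborhood protein -> precursor candidate filtering,
motif scanning and classification -> redundancy-weighted directon
association statistics.  ``write_reports`` emits the loci, cluster,
precursor and association tables as TSV plus the UPGMA tree in newick and
a run manifest; outputs are sorted deterministically so identical inputs
and configuration yield byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .association import (
    AssociationRecord,
    compute_locus_weights,
    filter_associations,
    weighted_association,
)
from .config import PipelineConfig
from .homolog import HomologClustering, cluster_homologs
from .locus import (
    Directon,
    GeneFeature,
    Locus,
    anchor_directon,
    extract_neighborhood,
)
from .precursor import (
    MotifPattern,
    PrecursorCall,
    candidate_filter,
    classify_precursor,
)
from .seqcore import SubstitutionMatrix


class PipelineInputError(ValueError):
    pass


@dataclass
class MineResult:
    config: PipelineConfig
    loci: list[Locus]
    directons: dict[str, Directon]  # locus_id -> anchor directon
    clustering: HomologClustering
    anchor_clusters: set[int]
    candidate_evidence: dict[int, object]
    precursor_calls: list[PrecursorCall]
    associations: list[AssociationRecord]
    associations_kept: list[AssociationRecord]
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]


def _checksum(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()


def run_mine(
    config: PipelineConfig,
    proteins: Mapping[str, str],
    features: Sequence[GeneFeature],
    anchor_ids: Iterable[str],
    reference_sets: Mapping[str, str] | None = None,
    motif_library: Sequence[MotifPattern] | None = None,
    annotations: Iterable[str] | None = None,
) -> MineResult:
    """Run the full mining pipeline on in-memory inputs.

    ``anchor_ids`` are product ids of the anchor (ATP-grasp) genes.  Raises
    ``PipelineInputError`` when no anchor gene is found among the features.
    """
    anchor_ids = set(anchor_ids)
    matrix = SubstitutionMatrix.blosum62()
    anchor_genes = [g for g in features if g.product_id in anchor_ids]
    if not anchor_genes:
        raise PipelineInputError("no anchor genes found")
    missing = {g.product_id for g in anchor_genes} - set(proteins)
    if missing:
        raise PipelineInputError(
            f"anchor proteins missing from FASTA: {sorted(missing)[:5]}"
        )

    # neighborhoods around every anchor gene
    loci = [
        extract_neighborhood(
            features, g.gene_id, config.neighborhood_window, locus_id=g.gene_id
        )
        for g in sorted(anchor_genes, key=lambda g: (g.contig_id, g.start))
    ]
    gene_by_id = {g.gene_id: g for g in features}

    locus_proteins: dict[str, str] = {}
    member_ranks: dict[str, int] = {}
    for locus in loci:
        for g in locus.genes:
            pid = g.product_id
            if pid not in proteins:
                raise PipelineInputError(f"protein {pid!r} missing from FASTA")
            locus_proteins[pid] = proteins[pid]
            r = abs(locus.rank_of(g.gene_id))
            member_ranks[pid] = min(member_ranks.get(pid, r), r)

    clustering = cluster_homologs(
        locus_proteins,
        matrix,
        tier1_threshold=config.tier1_identity,
        tier2_threshold=config.tier2_identity,
        depth_cutoff=config.depth_cutoff,
        h_consensus=config.h_consensus,
    )
    labels = clustering.labels()
    tier1_of = dict(
        zip(
            clustering.provenance["sequence_id"],
            clustering.provenance["tier1_cluster"],
        )
    )
    anchor_clusters = {
        labels[g.product_id] for g in anchor_genes if g.product_id in labels
    }

    # anchor directons and their family content
    directons: dict[str, Directon] = {}
    directon_families: dict[str, set[int]] = {}
    for locus in loci:
        d = anchor_directon(locus, config.directon_gap)
        directons[locus.locus_id] = d
        fams = {
            labels[gene_by_id[gid].product_id]
            for gid in d.gene_ids
            if gene_by_id[gid].product_id in labels
        }
        directon_families[locus.locus_id] = fams - anchor_clusters

    # redundancy weights from the tier-1 cluster of each locus anchor
    anchor_group = {
        locus.locus_id: int(tier1_of[locus.anchor.product_id]) for locus in loci
    }
    weights = compute_locus_weights(anchor_group)

    # precursor screen over non-anchor clusters
    non_anchor = [
        cl for cl in clustering.clusters if cl.cluster_id not in anchor_clusters
    ]
    evidence = candidate_filter(
        non_anchor,
        locus_proteins,
        member_ranks,
        max_len=config.max_precursor_length,
        max_rank=config.candidate_max_rank,
        majority=config.length_majority,
    )
    calls = [
        classify_precursor(
            cl,
            locus_proteins,
            evidence[cl.cluster_id],
            reference_sets=reference_sets,
            motif_library=motif_library,
            annotations=annotations,
            matrix=matrix,
            small_set=frozenset(config.small_set),
            hydrophobic_set=frozenset(config.hydrophobic_set),
            leader_window=config.leader_window,
            reference_id_thr=config.reference_identity,
            reference_cov_thr=config.reference_coverage,
        )
        for cl in non_anchor
    ]

    records = weighted_association(directon_families, weights)
    kept = filter_associations(
        records, config.assoc_min_loci, config.assoc_min_wfreq
    )

    checksums = {
        "proteins": _checksum(
            "".join(f">{k}\n{v}\n" for k, v in sorted(proteins.items()))
        ),
        "features": _checksum(
            "".join(
                f"{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.product_id}\n"
                for g in sorted(features)
            )
        ),
        "anchors": _checksum("".join(a + "\n" for a in sorted(anchor_ids))),
    }
    stage_counts = {
        "anchors": len(anchor_genes),
        "loci": len(loci),
        "locus_proteins": len(locus_proteins),
        "tier1_clusters": int(clustering.provenance["tier1_cluster"].nunique()),
        "tier2_clusters": len(clustering.tier2_clusters),
        "final_clusters": len(clustering.clusters),
        "candidate_clusters": sum(1 for e in evidence.values() if e.passed),
        "known": sum(1 for c in calls if c.status == "known"),
        "new": sum(1 for c in calls if c.status == "new"),
        "candidate": sum(1 for c in calls if c.status == "candidate"),
        "rejected": sum(1 for c in calls if c.status == "rejected"),
        "associations": len(records),
        "associations_kept": len(kept),
    }
    return MineResult(
        config=config,
        loci=loci,
        directons=directons,
        clustering=clustering,
        anchor_clusters=anchor_clusters,
        candidate_evidence=evidence,
        precursor_calls=calls,
        associations=records,
        associations_kept=kept,
        input_checksums=checksums,
        stage_counts=stage_counts,
    )


def _loci_table(result: MineResult) -> pd.DataFrame:
    rows = []
    for locus in result.loci:
        d = result.directons[locus.locus_id]
        rows.append(
            {
                "locus_id": locus.locus_id,
                "anchor_gene": locus.anchor_id,
                "contig_id": locus.anchor.contig_id,
                "n_genes": len(locus.genes),
                "directon_size": len(d.gene_ids),
                "truncated_left": locus.truncated_left,
                "truncated_right": locus.truncated_right,
            }
        )
    return pd.DataFrame(rows).sort_values("locus_id").reset_index(drop=True)


def _clusters_table(result: MineResult) -> pd.DataFrame:
    df = result.clustering.provenance.copy()
    df["is_anchor_cluster"] = df["final_cluster"].isin(result.anchor_clusters)
    return df.sort_values("sequence_id").reset_index(drop=True)


def _precursors_table(result: MineResult) -> pd.DataFrame:
    rows = []
    for call in result.precursor_calls:
        rows.append(
            {
                "cluster_id": call.cluster_id,
                "status": call.status,
                "reference_overlap": call.reference_overlap,
                "motif_match": call.motif_match,
                "annotation_flag": call.annotation_flag,
                "passed_filter": call.passed_filter,
                "conserved_doublet": call.conserved_doublet,
                "gg_and_leader_n30": call.gg_and_leader_n30,
                "n_leader_hits": len(call.leader_hits),
                "n_gg_hits": len(call.gg_hits),
                "n_core_hits": len(call.core_hits),
                "bond_candidates": ",".join(
                    f"{pos}:{res}" for pos, res in call.bond_candidates
                ),
                "thioether_candidates": ",".join(
                    str(p) for p in call.thioether_candidates
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)


def _associations_table(result: MineResult) -> pd.DataFrame:
    kept_ids = {r.family_cluster_id for r in result.associations_kept}
    rows = [
        {
            "family_cluster_id": r.family_cluster_id,
            "weighted_frequency": round(r.weighted_frequency, 10),
            "raw_count": r.raw_count,
            "passes_threshold": r.family_cluster_id in kept_ids,
        }
        for r in result.associations
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "family_cluster_id",
            "weighted_frequency",
            "raw_count",
            "passes_threshold",
        ],
    )
    return df.sort_values(
        ["weighted_frequency", "family_cluster_id"], ascending=[False, True]
    ).reset_index(drop=True)


def write_reports(result: MineResult, out_dir: str | Path) -> dict[str, str]:
    """Write the report bundle; stable column order and row sort, UTF-8."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "loci.tsv": _loci_table(result),
        "clusters.tsv": _clusters_table(result),
        "precursors.tsv": _precursors_table(result),
        "associations.tsv": _associations_table(result),
    }
    for name, df in tables.items():
        df.to_csv(out / name, sep="\t", index=False, lineterminator="\n")
    if result.clustering.tree is not None:
        (out / "tree.nwk").write_text(result.clustering.tree.to_newick() + "\n")
    manifest = {
        "tool": "graspmine",
        "version": __version__,
        "config": result.config.to_dict(),
        "input_checksums": result.input_checksums,
        "stage_counts": result.stage_counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    files = sorted(tables) + ["manifest.json"]
    if result.clustering.tree is not None:
        files.append("tree.nwk")
    return {name: str(out / name) for name in files}
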