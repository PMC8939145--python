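"""Genome feature handling: anchor-gene neighborhoods and directons.

A locus is the window of up to ten genes on each side of an anchor
(ATP-grasp) gene on the same contig, with signed neighbor ranks (negative
to the left of the anchor in genome coordinates).  Directons — maximal runs
of closely spaced genes transcribed in the same direction — serve as the
operon proxy for the association statistics.

Coordinates are 1-based inclusive on input (GFF3 convention) and exposed
as 0-based half-open internally via ``start0``/``end0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_WINDOW = 10
DEFAULT_DIRECTON_GAP = 100

FEATURE_TABLE_COLUMNS = [
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product_id",
]


@dataclass(frozen=True, order=True)
class GeneFeature:
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str
    strand: str
    product_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end


@dataclass(frozen=True)
class Locus:
    """Neighborhood of genes around an anchor, with signed ranks."""

    locus_id: str
    anchor_id: str
    genes: tuple[GeneFeature, ...]
    ranks: dict[str, int]  # gene_id -> signed rank, anchor at 0
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def anchor(self) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == self.anchor_id:
                return g
        raise KeyError(self.anchor_id)

    def rank_of(self, gene_id: str) -> int:
        return self.ranks[gene_id]


@dataclass(frozen=True)
class Directon:
    """Run of same-strand, closely spaced genes."""

    gene_ids: tuple[str, ...]
    strand: str
    span: tuple[int, int]  # 1-based inclusive over the run
    contains_anchor: bool = False


def extract_neighborhood(
    features: Iterable[GeneFeature],
    anchor_id: str,
    window: int = DEFAULT_WINDOW,
    locus_id: str | None = None,
) -> Locus:
    """Collect up to ``window`` genes on each side of the anchor gene.

    Only genes on the anchor's contig are considered; ranks count gene
    positions left (negative) and right (positive) of the anchor.
    Truncation at contig edges is flagged.
    """
    by_id = {g.gene_id: g for g in features}
    if anchor_id not in by_id:
        raise KeyError(f"anchor gene {anchor_id!r} not found in features")
    anchor = by_id[anchor_id]
    contig = sorted(
        (g for g in by_id.values() if g.contig_id == anchor.contig_id),
        key=lambda g: (g.start, g.gene_id),
    )
    idx = next(i for i, g in enumerate(contig) if g.gene_id == anchor_id)
    lo = max(0, idx - window)
    hi = min(len(contig), idx + window + 1)
    genes = tuple(contig[lo:hi])
    ranks = {g.gene_id: (lo + k) - idx for k, g in enumerate(genes)}
    return Locus(
        locus_id=locus_id if locus_id is not None else anchor_id,
        anchor_id=anchor_id,
        genes=genes,
        ranks=ranks,
        truncated_left=idx - lo < window,
        truncated_right=hi - 1 - idx < window,
    )


def assemble_directons(
    locus: Locus, max_gap: int = DEFAULT_DIRECTON_GAP
) -> list[Directon]:
    """Split the locus into maximal same-strand runs with gaps <= max_gap.

    The intergenic gap between adjacent genes is the number of bases
    strictly between them; a strand switch or a larger gap starts a new
    directon.  The directon containing the anchor is flagged.
    """
    genes = sorted(locus.genes, key=lambda g: (g.start, g.gene_id))
    directons: list[Directon] = []
    run: list[GeneFeature] = []

    def flush() -> None:
        if run:
            directons.append(
                Directon(
                    gene_ids=tuple(g.gene_id for g in run),
                    strand=run[0].strand,
                    span=(run[0].start, run[-1].end),
                    contains_anchor=any(
                        g.gene_id == locus.anchor_id for g in run
                    ),
                )
            )

    for g in genes:
        if run and (
            g.strand != run[-1].strand or g.start0 - run[-1].end0 > max_gap
        ):
            flush()
            run = []
        run.append(g)
    flush()
    return directons


def anchor_directon(
    locus: Locus, max_gap: int = DEFAULT_DIRECTON_GAP
) -> Directon:
    for d in assemble_directons(locus, max_gap):
        if d.contains_anchor:
            return d
    raise RuntimeError(f"locus {locus.locus_id}: no anchor directon")


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """Read the 6-column TSV dialect: contig, gene_id, start, end, strand,
    protein id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path}: missing columns {sorted(missing)}")
    return [
        GeneFeature(
            contig_id=row.contig_id,
            gene_id=row.gene_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            product_id=row.product_id,
        )
        for row in df.itertuples()
    ]


def write_feature_table(path: str | Path, features: Sequence[GeneFeature]) -> None:
    df = pd.DataFrame(
        [
            {
                "contig_id": g.contig_id,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product_id": g.product_id,
            }
            for g in features
        ],
        columns=FEATURE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gff3(path: str | Path, feature_type: str = "CDS") -> list[GeneFeature]:
    """Read CDS features from a GFF3 file.

    The gene id comes from the ID attribute; the protein id from the
    protein_id attribute when present, else the ID.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("protein_id", [gene_id])[0]
        out.append(
            GeneFeature(
                contig_id=feat.seqid,
                gene_id=gene_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product_id=product,
            )
        )
    return out


def write_gff3(path: str | Path, features: Sequence[GeneFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(features, key=lambda g: (g.contig_id, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};protein_id={g.product_id}"
            fh.write(
                f"{g.contig_id}\tgraspmine\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )
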