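"""Seeded generator of synthetic graspetide loci.

Emulates the study conditions the mining pipeline is exercised on:
divergent anchor (ATP-grasp-like) families, short precursor genes carrying
a planted Phhx(1,2)h leader motif, a GG-like small-residue cleavage doublet
and a core-peptide pattern, ancillary families co-occurring in the anchor
directon with controlled probabilities, unrelated decoy genes, and a
controllable fraction of near-identical (redundant) loci that exercises the
redundancy weighting.

Family divergence follows a random bifurcating tree with per-site
substitution at a given rate per branch; substitutions are drawn with
probability weighted by BLOSUM62 similarity so that families stay alignable
at moderate rates, as real protein families do.  Every output is a pure
function of (specification, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus import GeneFeature, write_feature_table, write_gff3
from .precursor import (
    BUNDLED_MOTIF_LIBRARY,
    DEFAULT_HYDROPHOBIC_SET,
    DEFAULT_LEADER_WINDOW,
    DEFAULT_SMALL_SET,
    MotifPattern,
    match_core_pattern,
)
from .seqcore import AMINO_ACIDS, SubstitutionMatrix, write_fasta

_CODON = 3  # nucleotides per residue when laying genes on a contig


@dataclass(frozen=True)
class PlantedFamilySpec:
    family_id: str
    root_length: int
    rate: float  # per-site substitution probability per branch
    n_members: int
    role: str  # anchor | precursor | ancillary | decoy

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError("rate must be in [0, 1)")
        if self.n_members < 1:
            raise ValueError("member count must be >= 1")


def _substitution_probs(matrix: SubstitutionMatrix) -> np.ndarray:
    """Row-stochastic 20x20 replacement distribution, zero diagonal,
    weighted by exp(score/2) so similar residues are preferred targets."""
    w = np.exp(matrix.scores / 2.0)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def _mutate(
    enc: np.ndarray, rate: float, rng: np.random.Generator, probs: np.ndarray
) -> np.ndarray:
    out = enc.copy()
    hit = rng.random(len(enc)) < rate
    for i in np.flatnonzero(hit):
        out[i] = rng.choice(20, p=probs[enc[i]])
    return out


def _decode(enc: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in enc)


def evolve_family(
    spec: PlantedFamilySpec,
    seed: int | np.random.Generator,
    matrix: SubstitutionMatrix | None = None,
    root: np.ndarray | None = None,
) -> dict[str, str]:
    """Generate family members along a random bifurcating tree.

    The root is i.i.d. uniform over the 20 residues unless supplied; each
    bifurcation replaces a random lineage with two children mutated from it
    at the per-site rate.  Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    probs = _substitution_probs(matrix)
    if root is None:
        root = rng.integers(0, 20, size=spec.root_length)
    lineages = [np.asarray(root)]
    while len(lineages) < spec.n_members:
        k = int(rng.integers(len(lineages)))
        parent = lineages.pop(k)
        lineages.append(_mutate(parent, spec.rate, rng, probs))
        lineages.append(_mutate(parent, spec.rate, rng, probs))
    rng.shuffle(lineages)
    lineages = lineages[: spec.n_members]
    return {
        f"{spec.family_id}_{k:03d}": _decode(enc)
        for k, enc in enumerate(lineages)
    }


# ---------------------------------------------------------------------------
# precursor synthesis


@dataclass(frozen=True)
class PlantedMotifs:
    """1-based inclusive coordinates of the planted motifs in a precursor."""

    leader: tuple[int, int]
    gg: tuple[int, int]
    core: tuple[int, int]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _instantiate_pattern(
    pattern: MotifPattern, rng: np.random.Generator
) -> str:
    out = []
    for charset, lo, hi in pattern.tokens:
        if charset is None:
            n = int(rng.integers(lo, hi + 1))
            out.append(_random_seq(rng, n))
        else:
            choices = sorted(charset)
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def synth_precursor(
    core_pattern: MotifPattern,
    seed: int | np.random.Generator,
    leader_window: int = DEFAULT_LEADER_WINDOW,
    max_len: int = 150,
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC_SET,
    small_set: frozenset = DEFAULT_SMALL_SET,
) -> tuple[str, PlantedMotifs]:
    """Build a precursor: leader with one planted Phhx(1,2)h within the
    N-terminal window, a GG-like doublet (always containing G), a core
    instantiating ``core_pattern``, and a short random tail."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    budget = 2 + (leader_window - 6) + 6 + 6 + 2 + core_pattern.max_length + 5
    if 2 + 5 + 2 + 2 + core_pattern.max_length > max_len:
        raise ValueError(
            f"core pattern {core_pattern.pattern!r} cannot fit in {max_len} residues"
        )
    hyd = sorted(hydrophobic_set)

    def pick(pool: Sequence[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    # leader: 'M' + random prefix, then P h h x{g} h
    motif_start = int(rng.integers(2, min(leader_window - 5, 16) + 1))
    gap = int(rng.integers(1, 3))
    motif = "P" + pick(hyd) + pick(hyd) + _random_seq(rng, gap) + pick(hyd)
    leader = "M" + _random_seq(rng, motif_start - 2) + motif
    leader_span = (motif_start, motif_start + len(motif) - 1)

    spacer = _random_seq(rng, int(rng.integers(2, 7)))
    gg_pos = len(leader) + len(spacer) + 1
    small = sorted(small_set - {"G"})
    doublet = "G" + pick(small) if rng.random() < 0.5 else pick(small) + "G"
    if rng.random() < 0.5:
        doublet = "GG"

    core = _instantiate_pattern(core_pattern, rng)
    core_start = gg_pos + 2
    tail_budget = max_len - (core_start + len(core) - 1)
    tail = _random_seq(rng, int(rng.integers(0, min(5, max(tail_budget, 0)) + 1)))

    seq = leader + spacer + doublet + core + tail
    if len(seq) > max_len:
        raise ValueError("length budget exceeded")  # pragma: no cover
    planted = PlantedMotifs(
        leader=leader_span,
        gg=(gg_pos, gg_pos + 1),
        core=(core_start, core_start + len(core) - 1),
    )
    return seq, planted


@dataclass(frozen=True)
class PrecursorFamilySpec:
    family_id: str
    core_pattern: MotifPattern
    rate: float = 0.05  # divergence outside the planted motifs


# ---------------------------------------------------------------------------
# locus sets


@dataclass
class GroundTruth:
    genes: pd.DataFrame  # locus, contig, gene, product, family, role, group
    motifs: dict[str, PlantedMotifs]  # product_id -> planted coordinates
    ancillary_probs: dict[str, float]
    seed: int

    def family_labels(self) -> dict[str, str]:
        return dict(zip(self.genes["product_id"], self.genes["family_id"]))

    def redundancy_groups(self) -> dict[str, int]:
        sub = self.genes.drop_duplicates("locus_id")
        return dict(zip(sub["locus_id"], sub["redundancy_group"]))


@dataclass
class LocusSet:
    proteins: dict[str, str]
    features: list[GeneFeature]
    anchor_ids: list[str]  # product ids of anchor genes
    locus_ids: list[str]
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "proteins.faa", self.proteins)
        write_feature_table(out / "features.tsv", self.features)
        write_gff3(out / "features.gff3", self.features)
        (out / "anchors.txt").write_text(
            "".join(a + "\n" for a in self.anchor_ids)
        )
        gt = self.ground_truth
        gt.genes.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                        lineterminator="\n")
        manifest = {
            "seed": gt.seed,
            "n_loci": len(self.locus_ids),
            "n_genes": len(self.features),
            "ancillary_probs": gt.ancillary_probs,
            "files": {
                "proteins": "proteins.faa",
                "features": "features.tsv",
                "gff3": "features.gff3",
                "anchors": "anchors.txt",
                "ground_truth": "ground_truth.tsv",
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest["files"]


@dataclass(frozen=True)
class _GenePlan:
    family_id: str
    role: str
    seq: str
    in_directon: bool
    side: int  # -1 upstream of anchor, +1 downstream; 0 anchor
    motifs: PlantedMotifs | None = None


def default_anchor_specs(n_branches: int = 3) -> list[PlantedFamilySpec]:
    """Anchor branches: long, within-branch divergence moderate (members of a
    branch stay above ~70% identity; branches are unrelated roots)."""
    return [
        PlantedFamilySpec(
            family_id=f"anchor{b}", root_length=160, rate=0.12, n_members=1, role="anchor"
        )
        for b in range(n_branches)
    ]


def default_precursor_specs() -> list[PrecursorFamilySpec]:
    """Six precursor families: two seeded from the bundled (known) core
    motifs, four with novel core patterns absent from the library."""
    lib = {p.name: p for p in BUNDLED_MOTIF_LIBRARY}
    novel = [
        MotifPattern("SxxSxxxKxxExxD", name="novel_core_1", region="core"),
        MotifPattern("KxxxExxxxSxD", name="novel_core_2", region="core"),
        MotifPattern("TxExxxxKxxxSS", name="novel_core_3", region="core"),
        MotifPattern("DxxxxSxxTxxE", name="novel_core_4", region="core"),
    ]
    specs = [
        PrecursorFamilySpec("prec_known_0", lib["chryseoviridin_core"]),
        PrecursorFamilySpec("prec_known_1", lib["branch1_core"]),
    ]
    specs += [
        PrecursorFamilySpec(f"prec_new_{i}", pat) for i, pat in enumerate(novel)
    ]
    return specs


def default_ancillary_probs() -> dict[str, float]:
    """Co-occurrence probabilities of ancillary families in the anchor
    directon, spanning frequent (transporter/peptidase-like) to rare."""
    return {"anc_peptidase": 0.6, "anc_spasm": 0.35, "anc_hlyd": 0.15, "anc_rare": 0.04}


def generate_locus_set(
    n_loci: int,
    seed: int,
    anchor_specs: Sequence[PlantedFamilySpec] | None = None,
    precursor_specs: Sequence[PrecursorFamilySpec] | None = None,
    ancillary_probs: Mapping[str, float] | None = None,
    redundancy_fraction: float = 0.2,
    directon_gap: int = 100,
    matrix: SubstitutionMatrix | None = None,
) -> LocusSet:
    """Generate ``n_loci`` synthetic anchor loci with ground truth.

    Each template locus holds one anchor gene, one or two precursor genes
    within two genes of the anchor in the same directon, ancillary genes
    included independently with their co-occurrence probabilities, and
    decoy genes placed outside the anchor directon (strand switch or a gap
    beyond the directon threshold).  A ``redundancy_fraction`` of loci are
    near-copies (low-rate re-evolution, anchor identity >= 95%) of template
    loci; the first locus puts its anchor at the contig edge.
    """
    if anchor_specs is None:
        anchor_specs = default_anchor_specs()
    if precursor_specs is None:
        precursor_specs = default_precursor_specs()
    if ancillary_probs is None:
        ancillary_probs = default_ancillary_probs()
    if not 0 <= redundancy_fraction < 1:
        raise ValueError("redundancy_fraction must be in [0, 1)")
    if any(not 0 <= p <= 1 for p in ancillary_probs.values()):
        raise ValueError("co-occurrence probabilities must be in [0, 1]")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    rng = np.random.default_rng(seed)
    probs = _substitution_probs(matrix)

    n_templates = max(1, int(round(n_loci * (1.0 - redundancy_fraction))))
    n_templates = min(n_templates, n_loci)

    # family roots
    anchor_roots = {
        sp.family_id: rng.integers(0, 20, size=sp.root_length)
        for sp in anchor_specs
    }
    anchor_rates = {sp.family_id: sp.rate for sp in anchor_specs}

    # Families whose core pattern is NOT in the bundled library must stay
    # clean of library motifs, otherwise a chance wildcard draw would turn a
    # planted-new family into a known one; rejection-sample those.
    library_core = [p for p in BUNDLED_MOTIF_LIBRARY if p.region == "core"]
    library_pats = {p.pattern for p in BUNDLED_MOTIF_LIBRARY}

    def _library_contaminated(seq: str, own: MotifPattern) -> bool:
        if own.pattern in library_pats:
            return False
        return any(match_core_pattern(seq, p) for p in library_core)

    prec_templates: dict[str, tuple[str, PlantedMotifs]] = {}
    for sp in precursor_specs:
        for _ in range(50):
            seq, planted = synth_precursor(sp.core_pattern, rng)
            if not _library_contaminated(seq, sp.core_pattern):
                break
        prec_templates[sp.family_id] = (seq, planted)
    prec_rates = {sp.family_id: sp.rate for sp in precursor_specs}
    prec_pattern = {sp.family_id: sp.core_pattern for sp in precursor_specs}
    anc_roots = {
        fam: rng.integers(0, 20, size=int(rng.integers(140, 220)))
        for fam in sorted(ancillary_probs)
    }

    # precursor families are tied to anchor branches round-robin
    branch_of_prec = {
        sp.family_id: anchor_specs[i % len(anchor_specs)].family_id
        for i, sp in enumerate(precursor_specs)
    }

    def mutate_seq(seq_or_enc, rate: float) -> np.ndarray:
        enc = (
            seq_or_enc
            if isinstance(seq_or_enc, np.ndarray)
            else np.array([AMINO_ACIDS.index(c) for c in seq_or_enc])
        )
        return _mutate(enc, rate, rng, probs)

    _none = MotifPattern("x", name="none")  # never in the library

    def clean_mutant(seq_or_enc, rate: float) -> str:
        """Mutate, rejecting draws that contain a library core motif by
        chance (non-precursor genes must stay inert in the known/new
        classification)."""
        for _ in range(50):
            seq = _decode(mutate_seq(seq_or_enc, rate))
            if not _library_contaminated(seq, _none):
                return seq
        return seq

    def clean_random(n: int) -> str:
        for _ in range(50):
            seq = _random_seq(rng, n)
            if not _library_contaminated(seq, _none):
                return seq
        return seq

    def precursor_member(
        fam: str, rate: float, base: str | None = None
    ) -> tuple[str, PlantedMotifs]:
        """Mutate a precursor template, then restore the planted motif
        residues so the motif round-trips exactly (noise-free planting)."""
        template, planted = prec_templates[fam]
        source = base if base is not None else template
        for _ in range(50):
            mutated = list(_decode(mutate_seq(source, rate)))
            for lo, hi in (planted.leader, planted.gg, planted.core):
                mutated[lo - 1 : hi] = template[lo - 1 : hi]
            seq = "".join(mutated)
            if not _library_contaminated(seq, prec_pattern[fam]):
                return seq, planted
        return seq, planted

    template_plans: list[list[_GenePlan]] = []
    for t in range(n_templates):
        branch = anchor_specs[t % len(anchor_specs)]
        anchor_seq = clean_mutant(
            anchor_roots[branch.family_id], anchor_rates[branch.family_id]
        )
        plans: list[_GenePlan] = []
        # upstream (left) decoys, outside the directon; omitted for the first
        # template so one anchor sits at a contig edge
        if t != 0:
            plans.append(
                _GenePlan(
                    family_id=f"decoy_long_{t}",
                    role="decoy",
                    seq=clean_random(int(rng.integers(160, 240))),
                    in_directon=False,
                    side=-1,
                )
            )
        # precursor genes at ranks -1/-2, in the anchor directon
        my_precs = [
            sp.family_id
            for sp in precursor_specs
            if branch_of_prec[sp.family_id] == branch.family_id
        ]
        # rotate so every family of the branch recurs across template loci
        shift = (t // len(anchor_specs)) % max(len(my_precs), 1)
        my_precs = my_precs[shift:] + my_precs[:shift]
        n_prec = min(len(my_precs), 1 + int(rng.random() < 0.4))
        for fam in my_precs[:n_prec]:
            pseq, planted = precursor_member(fam, prec_rates[fam])
            plans.append(
                _GenePlan(
                    family_id=fam,
                    role="precursor",
                    seq=pseq,
                    in_directon=True,
                    side=-1,
                    motifs=planted,
                )
            )
        plans.append(
            _GenePlan(
                family_id=branch.family_id,
                role="anchor",
                seq=anchor_seq,
                in_directon=True,
                side=0,
            )
        )
        # ancillary genes downstream within the directon
        for fam in sorted(ancillary_probs):
            if rng.random() < ancillary_probs[fam]:
                plans.append(
                    _GenePlan(
                        family_id=fam,
                        role="ancillary",
                        seq=clean_mutant(anc_roots[fam], 0.08),
                        in_directon=True,
                        side=1,
                    )
                )
        # downstream decoy outside the directon (large gap)
        plans.append(
            _GenePlan(
                family_id=f"decoy_short_{t}",
                role="decoy",
                seq=clean_random(int(rng.integers(60, 120))),
                in_directon=False,
                side=1,
            )
        )
        template_plans.append(plans)

    # redundant loci: re-evolve every protein of a template at a low rate
    all_plans: list[tuple[list[_GenePlan], int]] = [
        (plans, t) for t, plans in enumerate(template_plans)
    ]
    for _ in range(n_loci - n_templates):
        t = int(rng.integers(n_templates))
        copied = []
        for gp in template_plans[t]:
            if gp.role == "precursor":
                # keep motifs intact in redundant copies as well
                seq, planted = precursor_member(gp.family_id, 0.02, base=gp.seq)
                copied.append(
                    _GenePlan(gp.family_id, gp.role, seq, gp.in_directon,
                              gp.side, planted)
                )
            else:
                copied.append(
                    _GenePlan(gp.family_id, gp.role, clean_mutant(gp.seq, 0.02),
                              gp.in_directon, gp.side, gp.motifs)
                )
        all_plans.append((copied, t))

    proteins: dict[str, str] = {}
    features: list[GeneFeature] = []
    anchor_ids: list[str] = []
    locus_ids: list[str] = []
    gene_rows: list[dict] = []
    motifs: dict[str, PlantedMotifs] = {}

    for li, (plans, group) in enumerate(all_plans):
        locus_id = f"locus{li:04d}"
        contig = f"ctg{li:04d}"
        locus_ids.append(locus_id)
        pos = 1 + int(rng.integers(0, 50))
        prev_in_directon: bool | None = None
        for gi, gp in enumerate(plans):
            if gi > 0:
                if gp.in_directon and prev_in_directon:
                    gap = int(rng.integers(5, max(6, directon_gap - 19)))
                else:
                    gap = directon_gap + 150 + int(rng.integers(0, 250))
                pos += gap
            strand = "+" if gp.in_directon else "-"
            length_nt = len(gp.seq) * _CODON + _CODON
            pid = f"{locus_id}_g{gi}"
            feature = GeneFeature(
                contig_id=contig,
                gene_id=pid,
                start=pos,
                end=pos + length_nt - 1,
                strand=strand,
                product_id=pid,
            )
            features.append(feature)
            proteins[pid] = gp.seq
            if gp.role == "anchor":
                anchor_ids.append(pid)
            if gp.motifs is not None:
                motifs[pid] = gp.motifs
            gene_rows.append(
                {
                    "locus_id": locus_id,
                    "contig_id": contig,
                    "gene_id": pid,
                    "product_id": pid,
                    "family_id": gp.family_id,
                    "role": gp.role,
                    "redundancy_group": group,
                }
            )
            pos = feature.end + 1
            prev_in_directon = gp.in_directon

    gt = GroundTruth(
        genes=pd.DataFrame.from_records(gene_rows),
        motifs=motifs,
        ancillary_probs=dict(ancillary_probs),
        seed=seed,
    )
    return LocusSet(
        proteins=proteins,
        features=features,
        anchor_ids=anchor_ids,
        locus_ids=locus_ids,
        ground_truth=gt,
    )
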