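# Methods

This note documents the models and procedures implemented in `graspmine`,
the tunable parameters and their defaults, the design choices made where
the procedure was genuinely open, and what the synthetic test substrate
does and does not establish about real data.

## Pairwise alignment and identity

All substitution scoring uses BLOSUM62 over the standard 20-letter
alphabet; `X` is accepted and scores 0 against everything.  The alignment
engine is a Gotoh dynamic program with an affine gap model in which a gap
of length *k* costs `open + k·extend` (defaults 11/1, the BLAST
convention), in global (Needleman–Wunsch, end gaps penalized) and local
(Smith–Waterman) modes.  Traceback is deterministic: on ties, diagonal
beats the vertical move beats the horizontal move, and gap extension beats
re-opening.  The engine is validated against Biopython's independent
`PairwiseAligner` on random sequence pairs in the test suite.

Percent identity supports two conventions: identical positions divided by
the shorter sequence length (the default, matching the semantics of
BLASTCLUST-style identity/coverage clustering), or divided by the number of
columns where both rows are aligned.  Coverage of each sequence is the
number of mutually aligned residues over its full length.

Greedy centroid clustering additionally offers a fast identity kernel
built on edlib's bit-parallel edit-distance alignment, with identity
counted over all alignment columns (gaps included).  The column
denominator is deliberate: under an edit-distance alignment a short
sequence can embed much of itself into a long unrelated centroid, so a
shorter-sequence denominator would overcall identity for length-discordant
pairs.  The exact BLOSUM kernel is available via `identity="exact"` and
both kernels agree on the planted families used in testing.

## Consensus and homogeneity

For each alignment column, the consensus residue maximizes the sum of
BLOSUM62 scores against all non-gap residues in the column (ties broken
alphabetically; all-gap columns yield `-`).  Column homogeneity is

```
H = clip( (S̄ − S_rand) / (S_self − S_rand), 0, 1 )
```

where `S̄` is the mean score of the consensus residue against the column,
`S_self` its self-score, and `S_rand` its mean score against a uniform
residue distribution.  A uniformly conserved column scores 1; a random
column scores ≈ 0; the measure is monotone in conservation, which makes the
two printed thresholds meaningful: columns with `H < 0.5` are masked to
`x` in the consensus, and tree-building alignments retain only columns with
less than 50% gaps and `H > 0.1`.  The exact historical normalization
behind these thresholds is not fully specified in the literature this
reconstruction follows; the formula above is isolated in
`seqcore.column_homogeneity` so it can be swapped without touching callers.

## Multiple alignment

Within-cluster alignments use a center-star construction: every member is
globally aligned to the longest member and the pairwise alignments are
merged over the reference coordinates (insertions left-justified and
padded).  For the within-cluster identity ranges produced by the two-tier
clustering (members share ≥ 50% identity with a common representative)
this is adequate and exactly reproducible; an external aligner can be
plugged in behind the same `MultipleAlignment` contract when higher-quality
alignments of diverse clusters are needed.

## Homolog clustering

1. **Tier 1** — greedy centroid clustering at 0.9 identity.  Sequences are
   processed longest-first (ties by identifier) and join the first centroid
   they match, so the result is independent of input order.  Tier-1 groups
   define the redundancy groups used by the association weights.
2. **Tier 2** — the tier-1 representatives are clustered again at 0.5
   identity; each tier-2 cluster inherits all member sequences of its
   constituent tier-1 groups and gets an alignment, a consensus profile and
   a position-specific scoring profile (per-column mean BLOSUM score of
   each residue against the column; the mean keeps scores comparable
   across cluster sizes).
3. **Cross-scoring** — `s_AB` is the best local alignment score of the
   profile of cluster A against the consensus sequence of cluster B; both
   directions are computed, and `s_AA` is the profile scored against its
   own consensus.  Two gates standing in for the E-value logic of a real
   iterative profile search: pairs whose consensus sequences fall below
   20% quick identity are not scored at all, and cross-scores below twice
   the Karlin–Altschul random-score expectation `ln(n·m)/λ` (λ = 0.267,
   the gapped BLOSUM62 value) are treated as "no hit".  Gated or missing
   scores are clamped to a floor of 1 so the log-ratio below is defined.
4. **Distances** — `d_AB = −ln(max(s_AB, s_BA)/min(s_AA, s_BB))`, clamped
   to 0 when the best cross-score exceeds the smaller self-score.
5. **UPGMA** — standard average linkage; the merged node sits at half the
   pair distance and new distances are size-weighted means.  Ties merge
   the lexicographically smallest pair for determinism.  The
   implementation is checked against a naive average-linkage oracle and
   against SciPy's `linkage(..., "average")` cophenetic distances.
6. **Dissection** — the tree is cut at a height threshold; every maximal
   subtree whose root height is at or below the cutoff becomes one final
   cluster of homologs.  The default cutoff is `−ln(0.01)/2 ≈ 2.303`
   (printed as 2.3): under the distance transform, two clusters merge when
   their cross-score reaches 1% of the smaller self-score.  Partitions are
   nested in the cutoff.

Every sequence's path through tier 1 → tier 2 → final cluster is recorded
in a provenance table.

## Precursor screening

The candidate filter keeps clusters in which strictly more than 50% of
members are ≤ 150 residues long and at least one member is encoded within
two genes of an anchor (first or second neighbor on either side).

Motif scanning uses a small pattern language: residue letters, `x` for any
residue, residue classes `[DE]`, and variable gaps `x(n-m)`.  Matching
enumerates every gap assignment and reports all (overlapping) matches in
leftmost-longest order; the scanners are validated against an independent
regex-based oracle.  The leader motif is `Phhx(1,2)h` with the hydrophobic
set {A,C,F,I,L,M,V,W,Y} (configurable — the class is only loosely defined
chemically), searched in the N-terminal 30 residues.  Cleavage-site
scanning enumerates doublets over the small-residue set {G,A,S,C,E};
requiring a glycine in the doublet is off by default since non-canonical
doublets occur, and both modes are exposed.

Classification is cluster-wide and follows a fixed decision table over
four evidence flags:

| evidence | status |
|---|---|
| reference overlap (50% id / 50% cov single linkage) OR library core-motif match OR precursor annotation | known |
| else: passed candidate filter AND conserved small-residue doublet | new |
| else: GG doublet AND leader motif within the N-terminal 30 residues | candidate |
| else | rejected |

A "conserved doublet" is a pair of adjacent alignment columns, each with
homogeneity ≥ 0.5 and a small-residue consensus.  Singleton clusters never
qualify — a single sequence cannot exhibit conservation — so isolated
precursor-like ORFs surface through the GG-plus-leader "candidate" route
rather than as "new" families.  The bundled motif library contains the
four core/leader patterns this package ships
(`TxxxTxxDxxxxDD`, `TxxxTx(6-10)Dx(1-4)D`, `TxxxxDxxxTxKxPSDxD[DE]`,
`PFFARFL`); external reference motif sets are supplied through the pattern
file format.  The core region of a cluster is taken as the alignment
columns after the last conserved doublet (the cleavage site), or the whole
alignment when none is found; conserved S/T/D/E/K consensus positions in
that region are reported as lactone/lactam bond candidates and conserved
cysteines as thioether-donor candidates.  Actual linkage connectivity is
not predicted.

## Association statistics

For each locus, the directon containing the anchor (maximal run of
same-strand genes with intergenic gaps ≤ 100 bp — "closely spaced" is not
quantified in the source procedure; 100 bp is a common operon-prediction
heuristic and is configurable) defines the co-transcribed context.  Every
non-anchor family is counted at most once per locus.  The weighted
frequency divides the weight sum of the loci containing the family by the
total locus weight, where a locus weighs `1/n` of its anchor's tier-1
redundancy group — so duplicating every locus changes no weighted
frequency, which is the point of the weighting.  Families in more than 20
loci with weighted frequency ≥ 1% (0.01 as a fraction; published tables
sometimes render these values under a percent header while printing
fractions) are flagged as non-randomly associated.

## Synthetic data

The generator emulates the study conditions the pipeline is tested under:

- **Anchor branches** (default 3): unrelated 160-residue roots; each locus
  draws a branch member by per-site substitution at rate 0.12, keeping
  within-branch identity near 75–80% (well inside the 0.5 tier-2
  threshold, outside the 0.9 tier-1 threshold).  Substitutions are drawn
  with probability ∝ exp(BLOSUM62/2), which keeps families alignable the
  way real protein families are.
- **Precursor families** (default 6, ≤ 150 aa): a leader with one planted
  `Phhx(1,2)h` within the N-terminal window, a GG-like doublet, a core
  instantiating the family's pattern, and a random tail.  Two families
  instantiate bundled library motifs (planted "known"); four carry novel
  core patterns.  Family members diverge at rate 0.05 outside the planted
  motifs, which are restored after mutation — planting is noise-free, so
  scanner recall on planted coordinates is exactly 1.  Sequences of
  non-library families are rejection-sampled so no library motif occurs by
  chance; without this, the ~10⁻³–10⁻² per-sequence chance of a spurious
  library match would randomly flip planted-new families to "known".
- **Ancillary families**: included in the anchor directon independently
  with configured probabilities (defaults 0.6/0.35/0.15/0.04, spanning the
  frequent-transporter to rare-enzyme range), placed downstream of the
  anchor at directon-compatible gaps.
- **Decoys**: unrelated random proteins placed outside the anchor directon
  (strand flip or gap beyond the threshold), including long decoys that
  fail the 150-residue rule.  The first locus omits its upstream genes so
  one anchor sits at a contig edge.
- **Redundancy**: a configurable fraction of loci are near-copies of a
  template (every protein re-evolved at rate 0.02, anchor identity
  ≥ 95%), exercising the tier-1 weighting exactly as collection redundancy
  does.

All outputs (FASTA, 6-column feature TSV, GFF3, ground-truth table,
manifest) are byte-deterministic functions of the specification and seed.

**What passing tests do not show.**  The generator plants clean,
well-separated families with substitution-only divergence: no indels
inside families, no domain fusions, no shared domains between families, no
partial gene calls, and noise-free motif planting.  Perfect ARI and motif
recall on this substrate demonstrate the machinery is implemented
correctly, not that the thresholds would recover families at these rates
in real genome collections, where the hard cases (split families, shared
promiscuous domains, leaderless precursors) dominate the error budget.
Likewise, the rule-based screen will happily call a random short ORF next
to an anchor a "candidate" (and a conserved pair of such ORFs "new") —
in the original procedure such calls were subject to manual curation.

## Problem sizes and numerical choices

Default test and acceptance runs use 20 replicates of 50-locus sets for
clustering recovery, 200 loci for the association binomial check, and
10-locus sets for determinism — sizes at which the full pipeline runs in
seconds while every stage (redundancy, both tiers, tree dissection,
classification, weighting) is non-trivially exercised.  Profile scores are
computed on an integer grid at 10⁻⁶ resolution inside the shared DP core;
distance clamping at 0 and the score floor of 1 guard the log-ratio; UPGMA
and greedy clustering break all ties lexicographically so that every run
is reproducible bit-for-bit.  Reports are sorted deterministically and the
run manifest records the full configuration and input checksums (the
manifest deliberately contains no timestamps, so identical runs produce
byte-identical bundles).

## Known limitations

- The star alignment degrades for clusters whose members share < 40%
  identity; the contract allows swapping in an external aligner.
- The cross-score significance gate is an analytic stand-in for E-values;
  genuinely borderline remote homologies (detectable only by iterative
  profile search) are floored and end up in separate final clusters.
- Profile search is single-pass; iterative refinement is intentionally out
  of scope (a hook exists at the `ScoredProfile` boundary).
- Directons are computed within the extracted ±10-gene window, so a
  directon that extends beyond the window is truncated.
- Whether tier-2 greedy identity uses global or local alignment identity
  is configurable; the default is global.
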