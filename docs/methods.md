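# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Cluster records and summaries

A cluster is a contiguous annotated locus with ordered protein-coding
features.  Coordinates are 1-based inclusive throughout (the GenBank
convention; GFF3 shares it, so no shift happens at that boundary).  The
gene count of a cluster counts CDS features only — tRNA and regulatory
features are ignored, since comparative cluster tables count
protein-coding genes.  Cluster length is reported in kilobases to one
decimal, rounded half-even.  CDSs without a `/translation` qualifier are
translated with the bacterial code (NCBI table 11); ambiguous codons
become `X`, and an internal stop codon warns rather than errors, because
draft-genome annotations routinely contain them.  GFF3 reading accepts
single-segment, phase-0 CDS lines only: the loci handled here are
bacterial and intron-free, and a phase-broken CDS more likely indicates
a corrupted file than real biology.

## Alignment and percent identity

Global pairwise alignment uses the Needleman–Wunsch algorithm with
affine gap costs (a gap of length *k* costs `gap_open + (k−1)·gap_extend`),
executed by Biopython's `PairwiseAligner`.  Defaults: BLOSUM62 with gap
open −10 / extend −1 for proteins; match +2 / mismatch −3 with gaps
−5/−2 for nucleotides — widely used defaults approximating the settings
of interactive alignment tools.  Among co-optimal alignments the first
of the aligner's deterministic enumeration is used, so results are
reproducible run to run.

Percent identity is defined as `100 × identical residue pairs / total
alignment columns`, gap columns included.  Published cluster comparisons
rarely state their identity denominator (it is a tool default); the
column denominator is the conservative choice — it can only lower
identity relative to a shorter-sequence denominator — and it is recorded
in the run metadata so downstream readers know which convention the
numbers follow.  Near a sharp threshold (the 90% family rule) a
different denominator can flip borderline pairs; this is an inherent
limitation when reproducing tool-derived identity tables.

The center-star multiple aligner (center = sequence maximizing summed
pairwise identity, others merged under "once a gap, always a gap") is
deliberately simple; it serves to produce alignment slices for the
distance-based phylogenetics, not to compete with progressive aligners.

## Homolog families

Families are single-linkage connected components of the graph whose
edges join protein pairs with identity strictly greater than the
threshold (default 90).  Single linkage is the only clustering
consistent with the labelling rule "pairs above the threshold share a
label": the rule is transitive in effect, and average linkage would
split a chain A–B–C in which A–C falls below threshold.  The strict
inequality at the boundary is intentional — a pair at exactly 90.0 does
not join.

Family identity is summarized as both the minimum and the mean over all
member pairs (one decimal); a published table's single "% identity" per
family is ambiguous between the two, so claims of the form "the core
families exceed X%" are evaluated against the minimum, the stricter
reading.  Singleton families report the sentinel `n/a`.

Families are named against a catalog of canonical exemplars; the best
exemplar above the threshold wins, ties broken by highest identity then
lexicographically smallest label.  Unmatched families get fresh labels
with a category prefix inferred from the product annotation.  The
`core_families` operation exposes `required_fraction` (default 1.0)
because real data contains truncated clusters (one known *wel* cluster
lacks several core genes), and whether the "core" should tolerate such
absences is a judgement call left to the caller.

## Operon prediction

Predicted transcripts are maximal runs of consecutive same-strand
genes, ordered 5′→3′ along the cluster.  This is exactly the
orientation-based rule used in comparative cluster studies; an
optional maximum intergenic distance additionally breaks runs at large
gaps, since production operon callers use one, but the default leaves
it off so predictions rest on orientation alone.

## Motif scanning

Patterns use PROSITE-style syntax (`x` any residue, `[..]`
alternatives, `x(m,n)` bounded repetition, optional dashes), compiled
to regular expressions and scanned from every start position so
overlapping hits are reported; variable repeats match
leftmost-shortest.  Matching is case-insensitive, and an unknown
residue `X` in the protein never satisfies a literal or alternative —
only the wildcard — to avoid false motif calls on low-quality
translations.  The built-in library holds the four diagnostic motifs
(GxGxxG, WxWxIP, (N/D)DxxD, and the Rieske motif realized as
`C-x-H-x(15,17)-C-x-x-H`; the 15–17 spacing follows the canonical
consensus and is configurable).  The isonitrile-synthase core motifs are
not available in machine-readable form anywhere and are therefore left
to a user-supplied set rather than invented.

## Classification

The class rules encode which genes are diagnostic: P3 (the second
aromatic prenyltransferase, found only in ambiguine clusters) ⇒ *amb*;
any *wel*-specific family (M1–3, R3, E4, O11–19, U7, U8) ⇒ *wel*;
otherwise *hpi*.  *amb* outranks *wel* because no known cluster carries
both marker sets; a dual-marker input yields *amb* plus a logged
warning rather than an error.  Incompleteness is a flag
(`putatively_nonfunctional`, raised when configurable required-core
genes are missing), not a fourth class, reflecting that a truncated
cluster's product capability is uncertain rather than different.

## Phylogeny

Distances: Jukes–Cantor (JC69), `d = −(3/4) ln(1 − 4p/3)` with pairwise
deletion of gap/ambiguous columns; pairs at `p ≥ 0.75` are outside the
model's domain and raise an error naming the taxa.  The distance model
is configurable (uncorrected p-distance included, and used for protein
trees such as the prenyltransferase tree) because GUI tree builders
rarely document their default.

Tree building is Saitou–Nei neighbour joining with a deterministic
tie-break (smallest active index pair at equal Q) and negative branch
lengths clamped to zero with a warning — the common convention, chosen
over redistributing length to neighbours.  NJ is exact on additive
matrices, which the test suite exploits as an oracle.

Bootstrap: alignment columns are resampled with replacement (seeded),
each replicate re-distanced and re-joined, and each internal edge of
the full-data tree is annotated with the percentage of replicates
containing the same bipartition.  Supports are mapped onto the
full-data tree, not a consensus tree, matching how interactive tree
builders annotate.  Replicates whose resampled alignment saturates a
pair are skipped and the denominator adjusts.  Monophyly of a taxon set
is tested after rooting on the outgroup edge: the set is monophyletic
iff it is exactly the leaf set of some clade.

Default analysis sizes follow the 16S use case: a 929-column alignment
slice and 100 bootstrap replicates.

## Exact mass

Monoisotopic mass sums most-abundant-isotope masses (C 12 exactly,
H 1.00782503, N 14.00307401, O 15.99491462, S, P, Cl) over a
Hill-notation formula and reports four decimals; the neutral-molecule
convention (no electron-mass correction) is used because reported
"expected m/z" values for small molecules are conventionally the
neutral monoisotopic mass — for C11H8N2 this gives 168.0687 Da.
Nominal adduct m/z uses integer isotope numbers ([M−H] subtracts one
hydrogen): m/z 167 for the indole-isonitrile.  `ppm_difference` is
`10⁶·|obs−exp|/exp`.

## Synthetic data

The generator realizes the structure the analysis assumes, under fixed
study conditions:

- **Protein families.**  A random ancestor (always starting with M);
  member 0 is the ancestor, each further member substitutes
  `round((1−t/100)·L)` uniformly chosen positions with distinct
  residues.  Ancestor-to-member identity therefore equals the target
  exactly (substitution-only, so the column-denominator identity has no
  gap ambiguity); member-to-member identity is lower by up to twice the
  per-member divergence, which keeps all pairs within ±5 points of the
  target for targets ≥ 90 and L ≥ 100.  Divergence is substitution-only
  by design; an indel mode would decouple target from realized identity.
- **The nine-cluster study preset** (`study_preset_config`): two *hpi*,
  two *amb* (the same organism represented twice, as in the source
  cluster tables) and five *wel* clusters.  All nine carry the 19-gene
  conserved core with per-family identity targets drawn once from
  97–99.5% (seeded), so every core family realizes > 92% minimum
  pairwise identity; the amb pair adds P3; wel clusters add M1–3, R3,
  E4, O12 and a halogenase H with the FAD- and tryptophan-binding
  motifs spliced in at recorded positions (a Rieske motif goes into
  O12).  The I2 family ancestor is derived from I1's at ~80% identity,
  mirroring the duplicated isonitrile synthase pair that stays below
  the 90% family threshold while remaining recognizably related.  The
  conserved 15-gene block is laid out as one strand run, marker and
  transporter genes on the opposite strand, and the regulators R1/R2 as
  separate singleton transcripts.  Protein lengths default to 120
  residues (160 for H, 140 for O12) — long enough for ±1-substitution
  identity granularity (~0.8%) and small enough that the all-vs-all
  alignment of ~220 proteins completes in seconds.
- **DNA realization.**  One fixed codon per amino acid plus a TAA stop,
  reverse-complemented for minus-strand genes, with 30–80 nt random
  spacers.  Codon usage, promoters and regulatory signal are not
  modelled — the records exercise parsers and coordinate arithmetic,
  not gene finders.
- **16S alignments.**  A uniform random root sequence evolved along a
  user tree with the exact JC69 transition kernel (per-branch change
  probability `¾(1−e^{−4d/3})`, uniform over the three other bases), so
  evolving along consecutive branches composes correctly.  Alignments
  are gap-free and rate-homogeneous across sites; real 16S data has
  indels, conserved stems and rate variation, so passing recovery tests
  demonstrates correctness of the estimator chain, not robustness to
  alignment error.

All randomness descends from one integer seed through spawned
generators (ancestors, family members, intergenic DNA are independent
streams), so the same seed reproduces byte-identical files while the
sub-simulations remain individually reproducible.

## Determinism and numerical choices

Family order, table row order (category prefix, then number), transcript
numbering and JSON key order are all fixed; co-optimal alignment and NJ
ties break deterministically; bootstrap resampling is seeded.  A rerun
of the pipeline with the same config and seed reproduces a byte-identical
report bundle, and the run metadata records every threshold, seed and
convention needed to do so.

## Known limitations

- Identity values near the 90% threshold depend on the identity
  denominator and the aligner's gap parameters; reproducing numbers
  produced by other tools may differ by a few tenths of a percent.
- The center-star MSA is adequate for closely related sequences only.
- JC69 underestimates distances under unequal base frequencies or
  transition/transversion bias; the p-distance alternative is provided
  but no richer substitution models are.
- The classifier is a presence/absence rule set: it cannot detect a
  class whose markers were missed by annotation, and it inherits any
  family-naming errors upstream.
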