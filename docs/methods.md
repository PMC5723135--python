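# Methods

## Problem setting

Aquatic oligochaetes (Naididae, Lumbriculidae, Enchytraeidae, ...) are
sediment-quality indicators whose morphological identification is slow,
requires mature specimens, and misses cryptic species. Reference databases
of mitochondrial COI barcodes sidestep this: specimens are assigned to
*lineages* — clusters of sequences delimited by a divergence threshold —
which may correspond to morphospecies or to cryptic species within them.
`barcodelim` implements the delimitation arithmetic such a database needs:
corrected pairwise distances, threshold clustering with taxon-specific
cutoffs, secondary-marker arbitration of borderline splits, per-lineage
divergence statistics, matching against an existing reference library, and
divergence-based dereplication for compact tree figures.

## Distance model

Distances are Kimura two-parameter (K2P). For a sequence pair let P and Q
be the proportions of compared sites differing by a transition (A↔G, C↔T)
and a transversion respectively; then

    d = −1/2 · ln(1 − 2P − Q) − 1/4 · ln(1 − 2Q)

Sites are compared under **pairwise deletion**: per pair, only positions
where both sequences carry an unambiguous A/C/G/T enter the counts; gaps,
`N` and IUPAC ambiguity codes are masked for that pair only. Complete
deletion (drop every column with any missing state) is available via
`build_matrix(..., deletion="complete")`. Ambiguity codes are treated as
missing rather than fractionally matched — their frequency in curated
Sanger barcodes is negligible and fractional matching would complicate the
estimator for no practical gain.

When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the logarithms diverge
(**saturation**): the pair's distance is carried as `+inf`, which can never
fall below a threshold, so saturated pairs never link clusters —
a deliberately conservative splitting behaviour. A pair with *zero*
comparable sites is a distinct condition (`UndefinedDistanceError` in the
scalar API; flagged saturated + low-coverage in matrices). Pairs sharing
fewer than `min_sites` (default 100) comparable sites are flagged
low-coverage and logged; they still cluster.

Distances are fractions internally everywhere; percent appears only in
reports and at the CLI boundary (one documented conversion point,
`cli.pct`).

## Delimitation

**Clustering rule.** Single linkage at an inclusive threshold: two
specimens share a lineage iff a chain of pairs each with d ≤ t connects
them. Single linkage is the rule implied by stating that lineages are
"separated by more than t": the between-lineage single-link distance
exceeds t exactly when no chain crosses. Complete linkage is offered as a
policy option for users who prefer compact clusters.

**Thresholds.** Default t = 10% COI divergence. Genus-specific overrides
(default: *Nais* and *Uncinais* at 8%, where morphologically distinct
species diverge by only 8–9%) are applied as a second pass *inside* each
default-threshold block: any block containing an override-genus specimen
is re-partitioned internally at the minimum applicable override. The
two-pass scheme keeps the result a true partition even when a block mixes
genera with different thresholds (a global per-pair threshold could create
non-transitive link relations).

**Doubtful zone.** A split whose between-lineage single-link distance lies
in (10%, 13.5%] is not trusted on COI alone when the two lineages show no
morphological difference — operationalized as: both sides share a
non-empty morphospecies label, or every member on both sides is
unidentifiable (empty label). Such pairs are resolved with a secondary
marker (ITS2, which evolves much more slowly than COI in these taxa): the
split is **merged** when the maximum ITS2 divergence across it is at or
below `secondary_merge_tolerance` (default 0 — strictly identical
sequences), **kept separate** when it exceeds it, **unresolved** when
either side lacks ITS2. Merges are applied transitively; every decision is
written to the provenance log. The 13.5% upper bound has no mechanistic
justification and is exposed as a parameter.

**Lineage ids** are canonical and deterministic: blocks sorted by their
lexicographically smallest member, ids `L01, L02, ...` (zero-padded to the
block count). Permuting the input order changes neither memberships nor
ids.

**Statistics** per lineage: maximum intra-lineage divergence (undefined
for singletons — printed `NC`), minimum inter-lineage divergence (minimum
from any member to any non-member; undefined with one lineage — `NA`),
specimen count, and the count of *morphologically identified* members
(non-empty morphospecies label AND mature flag — immature specimens cannot
be reliably identified in most of these families). ITS2 intra-lineage
maxima are reported where at least two members carry the marker.

## Reference matching and cryptic complexes

A query lineage matches a reference entry when the minimum K2P distance
over all (member, reference) pairs is ≤ 10% (configurable); otherwise the
lineage is flagged new to the library. Ties between reference labels break
lexicographically; a lineage within threshold of two or more distinct
labels is flagged ambiguous rather than auto-resolved (such conflicts need
expert morphology). A **cryptic complex** is any morphospecies label whose
bearers are split over ≥ 2 delimited lineages.

## Dereplication and trees

For figure display, sequences are collapsed by single linkage at *strictly
less than* the cutoff (default 5% and 1%), so sequences "separated by ≥
cutoff" are all retained. Each block is represented by its
lexicographically smallest id, labelled `<id> <k> ind` where k is the
block size *including* the representative. The convenience tree is plain
neighbor joining (delegated to scikit-bio; negative branch lengths clamped
to zero), serialized as newick with 6-decimal branch lengths by default.
Likelihood inference, model selection and bootstrapping are deliberately
out of scope — the dereplicated FASTA and PHYLIP-style lower-triangle
matrix exports feed external programs.

## Synthetic data generator

`simulate_dataset` produces datasets with known truth under the exact K2P
substitution process (closed-form transition probabilities; transition
rate = `kappa` × each transversion rate; branch lengths in expected
substitutions/site; uniform root composition — the model's stationary
distribution). The genealogy is star-within-star: lineage ancestors at
`inter_depth/2` from one root, member tips at `intra_depth/2` from their
ancestor. Defaults — 5 lineages × 4 members, 658 bp (the standard COI
Folmer fragment), kappa 2, 2% within / 18% between — put the data firmly
on either side of the 10% threshold, emulating the barcode gap the
threshold method assumes.

The **doubtful-pair scenario** grows the last two lineages from a shared
sub-ancestor. Because the link distance is a minimum over cross pairs, the
naive placement at `(target − intra)/2` per side undershoots the target;
the generator therefore redraws the pair's tips until the *realized* link
is within `link_tolerance` (default ±1%) of the target — the scenario
specifies a link divergence, and conditioning is how a finite-length
simulation delivers it. Deterministic for a fixed seed. ITS2 for the pair
is emitted byte-identical or diverged by a fixed amount; ITS2 evolution is
not modelled further since the pipeline only consumes its distances.

What the generator does **not** emulate: indels and alignment error, codon
structure and among-site rate heterogeneity of real COI, uneven Sanger
read trimming (missing data), contamination, and coalescent genealogies
(lineage depths are fixed, not drawn). A green recovery test therefore
establishes that the pipeline inverts its own stated world — clean
barcode-gapped data — not that any particular threshold is right for a
real fauna.

## Numerical choices

- Threshold comparison is inclusive (link iff d ≤ t); the dereplication
  cutoff is strict (collapse iff d < c). Both match the respective
  "separated by more/at least" statements being reproduced.
- `-0.0` from `ln(1) = 0` is canonicalized to `+0.0`.
- Report precision defaults to 2 decimal percent, configurable; mixed
  historical precisions are not mimicked.
- Seeds are mandatory in the generator; the acceptance script derives all
  randomness from its `--seed`.

## Known limitations

- Single linkage chains: a gradual series of intermediates can fuse
  well-separated extremes (observed in real data as within-lineage maxima
  above the threshold, e.g. 10.7% or 13.3% spans); this is inherent to the
  rule, and the doubtful-zone machinery is the guard rail.
- No automatic threshold discovery (ABGD/ASAP) or coalescent delimitation
  (GMYC/bPTP); thresholds are curator-supplied policy.
- Morphology enters only through curator labels; the package does not
  score characters.
- Reference matching is local; claims of "new to the database" are
  relative to the supplied library, whose coverage the report states.
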