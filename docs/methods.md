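# Methods

## Distance model

Distances are Kimura 2-parameter (K2P): substitutions are split into
transitions (A↔G, C↔T) and transversions, and the distance between two
sequences is

    d = -1/2 · ln( (1 - 2P - Q) · sqrt(1 - 2Q) )

with P = s/L and Q = v/L the transition and transversion difference
proportions over the L sites where both sequences carry an unambiguous
A/C/G/T. K2P assumes equal base frequencies and no rate variation across
sites; it is the conventional choice for COI barcoding and is kept as the
single distance model (p-distance, TN93 etc. are out of scope).

Conventions:

- **Pairwise deletion.** Sites with a gap or IUPAC ambiguity code in either
  sequence of a pair are excluded for that pair only, so short or partially
  ambiguous records reduce L rather than shrinking the whole alignment.
  Ambiguity codes are never partially matched (an R is excluded, not counted
  as half a transition) — full determinism, no fractional counts.
- **Saturation.** When `1-2P-Q ≤ 0` or `1-2Q ≤ 0` the logarithm is undefined;
  the pair's distance becomes `+inf` with a logged warning rather than an
  exception, so one degenerate public record cannot abort a 600-sequence run.
  `+inf` pairs are excluded from minima/maxima/means (their count is
  reported), never create clustering edges (they sit "above any cutoff"),
  and are imputed as the maximum finite distance when a full matrix is
  required for tree building.
- Sequences must be pre-aligned (equal length). COI barcodes are
  protein-coding and effectively indel-free, so alignment is not part of the
  pipeline; `trim_shared_window` trims records to a common window when their
  start offsets in a shared coordinate frame are known, and
  `min_length_filter` (default 400 nt ungapped) screens short public
  records.

## Divergence summaries

`species_extremes` reports, per species, the maximum intraspecific distance
and the distance to the nearest heterospecific individual. The nearest
heterospecific is searched across the whole dataset by default
(`congeners_only=True` restricts it to the same genus). Singletons have no
intraspecific pair: their `max_intra` and ratio are undefined (`None`,
printed `-`) and they are excluded from conspecific summaries.

`rank_distributions` classifies every pair at the *lowest* taxonomic rank the
two specimens share — conspecific, congeneric, consubfamilial, confamilial —
so the categories are mutually exclusive and their pair counts sum to the
total. Pairs whose members are in different families fall into an extra
`heterofamilial` category (absent for single-family datasets) so the
partition property holds on arbitrary tables.

`flag_species` flags a species as a SPLIT_CANDIDATE when `max_intra` exceeds
the split threshold and as a MERGE_CANDIDATE when `min_inter` falls below the
merge threshold (both default 0.04, tied to the 4% final MOTU cutoff; both
strict inequalities). If a species somehow triggers both, the split flag
wins; the evidence dictionary always carries both numbers.

## MOTU clustering

MOTUs at cutoff t are the connected components of the graph with an edge for
every finite pair with d ≤ t (single linkage / chain rule, the behaviour of
threshold-clustering barcoding tools). The cutoff is applied as `≤`.
Complete linkage — every within-MOTU pair within the cutoff — is available
behind a flag for sensitivity analysis. MOTU numbering is deterministic:
components are numbered by the smallest contained specimen index.

The cutoff sweep (default 0–25% in 0.5% steps) yields a non-increasing
richness curve; `plateau` returns the longest maximal run of constant
richness, excluding the degenerate all-one-MOTU run, with ties broken toward
the lower cutoff range. The final partition defaults to the restrictive 4%
cutoff, which screens lumped taxa more aggressively than the plateau centre.

`compare_partition` reconciles a partition with the a-priori morphospecies:
a species wholly inside one MOTU containing no other named species is a
MATCH; a species spanning k > 1 MOTUs is SPLIT(k), its specimens renamed
"<species> A", "<species> B", … with parts ordered by MOTU size descending,
then by smallest specimen index; species sharing a MOTU are LUMPED.
Specimens without an a-priori name do not affect these statuses: one inside
a single named species' MOTU is reported as assignable to that species, and
MOTUs containing only unassigned specimens are listed as putative
new/unreported species.

## Tree inference and monophyly

Neighbor joining follows Saitou–Nei: the pair minimizing
`Q(i,j) = (n-2)·d(i,j) − Σd(i,·) − Σd(j,·)` is joined at each step, with
branch lengths from the two-point formulas. Ties in Q are broken toward the
lexicographically smallest pair of subtree representative labels (the
smallest leaf id in each subtree), making the topology deterministic across
platforms. Negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving the joined pair's path length.
The result is an unrooted tree with a trifurcating seed node.

Bootstrap supports are Felsenstein column resampling: alignment columns are
drawn with replacement, the matrix and tree recomputed, and each internal
edge of the reference tree labelled with the percentage of replicates whose
tree contains the same leaf bipartition. A replicate in which some sequence
has no finite distance to anything is skipped with a warning and the
denominator adjusted. Everything is deterministic given the seed, and
supports are invariant under permutation of the input order.

Monophyly is assessed after rooting on the outgroup leaf's edge (midpoint of
that edge): a species is monophyletic iff the smallest rooted clade spanning
its members contains no heterospecific leaf; otherwise the foreign leaves
are listed as intruders. The outgroup's own species is excluded from the
report — rooting from inside a species makes its remaining members
paraphyletic by construction, so any verdict there would be a rooting
artifact. Root on a different outgroup to assess that species.

## Synthetic communities

The simulator generates the hierarchical structure of a regional barcoding
survey. One random root sequence (uniform base composition, as K2P assumes)
is evolved into genus ancestors, species ancestors, and individuals; each
branch is simulated by drawing per-site substitutions from the K2P transition
probabilities for that branch's expected divergence (matrix-exponential site
sampling, not discrete generations), so expected K2P distances are controlled
exactly and add along paths. Genus ancestors descend from a single family
root at `genus_expected_d/2` each — independent random genus roots would put
between-genus distances at or beyond K2P saturation, which no real
single-family dataset shows.

Defaults (chosen once, as the study conditions): 650 bp, kappa = 3,
within-species expectation 1%, between-species-within-genus 15%, between-
genus 25%, 4 genera × 5 species × 5 individuals. Note the realized congeneric
expectation is `inter + intra` (≈16%) because paths between individuals also
traverse the two within-species stems. The `paperlike` preset emulates a
survey of ~60 species in 20 genera with skewed (geometric) abundance between
1 and 20 individuals per species (~300–330 specimens), ~8% of specimens
masked as a-priori unidentified, and one species carrying a divergent
heteroplasmic (M-type) lineage 14% away — the doubly-uniparental-inheritance
pattern of some bivalves — which downstream flagging reports as a split
candidate.

What the simulator does **not** emulate: rate variation across sites and
lineages, codon structure and selection, base-composition bias, indels and
sequencing errors, geographic population structure, and incomplete lineage
sorting. Passing tests therefore demonstrate algorithmic correctness and
behaviour under idealized K2P evolution with a clean barcoding gap — not
performance on real data whose gap may be blurred by any of the above. The
heteroplasmic lineage descends from its species' ancestor, so the split
species remains a clade on the true tree; truly non-monophyletic
morphospecies (the misidentification scenario) are constructed in tests by
relabelling.

## Numerical choices and degenerate inputs

- K2P at s = v = 0 returns exactly 0.0; `L = 0` (no comparable sites) is an
  error in the scalar API and `+inf` in the bulk matrix builder.
- Distance matrices are validated as symmetric with a zero diagonal and at
  least 2 ids; richness sweeps round cutoffs to 12 decimals to avoid
  floating-point step drift.
- Sweeps with all distances equal produce a flat curve; `plateau` on a
  strictly decreasing curve returns the first single-point run with a
  warning.
- NJ requires n ≥ 3; n = 3 resolves by the three-point formulas (the first
  join is a full tie, resolved lexicographically).
- Newick serialization is hand-rolled (branch lengths via `%.10g`, supports
  as internal labels) so write → read → write is byte-identical; parsing is
  done by dendropy.
- Reports print percentages with two decimals; TSV is the single report
  dialect.

## Problem sizes used in tests

The test and acceptance runs use communities of 20 species × 5 individuals
(100 sequences) for recovery statistics over 100 seeds, a ~300-specimen
survey-scale community for the divergence summaries, 312- and 622-sequence
sets for the pair-count identities, bootstrap with 100 replicates on
6-sequence sets, and oracle suites up to n = 200 (clustering) and n = 12
(NJ). These sizes give stable statistics at interactive runtimes; all scale
linearly or quadratically to full survey sizes.
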