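# motukit

DNA-barcoding species delimitation for COI barcode surveys.

Morphology alone often fails to delimit species in groups with plastic or
overlapping shell/body characters (marine bivalves such as venus clams are a
classic case). A standardized ~650 bp fragment of the mitochondrial COI gene
— the DNA barcode — offers a fast molecular proxy: conspecific barcodes are
usually far more similar to each other than to barcodes of any other species,
and the divergence range separating the two distributions (the *barcoding
gap*) lets sequences be sorted into molecular operational taxonomic units
(MOTUs) that can be confronted with the morphology-based taxonomy.

`motukit` implements that complete analysis as a tested Python library and
CLI:

- **K2P distances** — Kimura 2-parameter distances with pairwise deletion of
  gapped/ambiguous sites: with transition proportion *P* and transversion
  proportion *Q* over the *L* comparable sites,
  `d = -½·ln((1-2P-Q)·√(1-2Q))`. Saturated pairs become `+inf` instead of
  aborting the run.
- **Divergence statistics** — per-species maximum intraspecific vs. minimum
  interspecific distance (with split/merge flagging), distance distributions
  per shared taxonomic rank (conspecific / congeneric / consubfamilial /
  confamilial), and the raw pairwise-distance histogram.
- **MOTU clustering** — single-linkage threshold clustering (two specimens
  share a MOTU if connected by a chain of pairs each within the cutoff),
  cutoff sweeps with plateau (barcoding-gap) detection, and reconciliation of
  MOTUs with the a-priori morphospecies: MATCH / SPLIT (with automatic
  "Species A"/"Species B" provisional renaming) / LUMPED, placement of
  unidentified specimens, and detection of putative new species.
- **NJ tree + monophyly** — Saitou–Nei neighbor joining with deterministic
  tie-breaking, Felsenstein bootstrap supports, and per-species monophyly
  assessment on an outgroup-rooted tree.
- **Community simulator** — COI-like sequence communities evolved under the
  Kimura model with controlled within-species, between-species and
  between-genus divergences, so the whole pipeline is testable end to end
  without any sequence downloads.

## Worked example

Simulate a small community (2 genera × 3 species × 4 individuals) and run the
full analysis:

```bash
motukit simulate --n-genera 2 --species-per-genus 3 --individuals 4 \
    --seed 11 --out-fasta community.fasta --out-taxonomy taxonomy.tsv
# wrote 24 sequences, 6 species

motukit run --fasta community.fasta --taxonomy taxonomy.tsv \
    --outdir results --bootstrap 100 --seed 11
# wrote 12 artifacts to results
```

`results/` then contains the distance table, divergence reports, MOTU
partition and curve, the bootstrapped NJ tree (Newick) and the monophyly
report. A few of the numbers and what they mean:

```text
$ head -4 results/species_extremes.tsv
species       n_individuals  max_intra  min_inter  ratio
Genus01 sp01  4              0.009290   0.139302   0.066689
Genus01 sp02  4              0.009304   0.139302   0.066793
Genus01 sp03  4              0.012413   0.144681   0.085796
```

Every species' deepest within-species divergence (~1%) is far below its
distance to the nearest heterospecific individual (~14%), so the ratio is
≪ 1 and no species is flagged for splitting or merging.

```text
$ head -3 results/rank_distributions.tsv
rank         n_pairs  min       mean      max       n_saturated
conspecific  36       0.001540  0.008307  0.014005  0
congeneric   96       0.139302  0.160190  0.181613  0

$ cat results/plateau.tsv
cutoff_low  cutoff_high  richness
0.015       0.135        6
```

Conspecific and congeneric distances do not overlap; across the whole
divergence gap (cutoffs 1.5–13.5%) the MOTU count is constant at 6 — the true
species number:

```bash
$ motukit motu community.fasta --cutoff 0.04 --out motus.tsv
6 MOTUs at cutoff 0.040
```

and all six species are monophyletic on the bootstrapped NJ tree
(`results/monophyly.tsv`).

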