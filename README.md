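# barcodegap

Distance-based species delimitation for DNA barcodes, built around the
analysis that resolved the *Bemisia tabaci* (sweet potato whitefly) species
complex: pairwise genetic distances over an aligned COI barcode window,
multi-level divergence profiling, barcode-gap detection, threshold
clustering into putative species, discriminant-analysis validation with
leave-one-out cross-validation, and cross-gene marker comparison. A
Kimura-2-parameter sequence simulator with known truth makes every stage
testable without any sequence downloads.

Intended for molecular taxonomists and entomologists working with COI (or
any mitochondrial barcode) alignments who want a deterministic, scriptable
alternative to spreadsheet/SPSS/MEGA workflows for threshold-based species
delimitation.

## The method

For each sequence pair, sites where either sequence has a gap or ambiguous
base are excluded (pairwise deletion), and the remaining differences are
split into transitions (A↔G, C↔T) and transversions. With transition and
transversion proportions *P* and *Q*, the Kimura-2-parameter distance is

    d = -1/2 · ln[(1 - 2P - Q) · √(1 - 2Q)]

(the uncorrected p-distance *P + Q* is also available). The pipeline then:

1. trims the alignment to the 3′-most *w* bases of a reference sequence
   (default 650 bp, the standard COI barcode window) and collapses duplicate
   haplotypes (byte-identical sequences);
2. partitions all pairwise distances by taxonomic level (within species /
   within genus between species / within family between genera) and
   summarizes each level (avg/min/max %, number of comparisons);
3. locates the **barcode gap** — the widest empty interval in the
   distance distribution inside a search window (default 1–10%);
4. delimits putative species at a threshold *t* as connected components of
   the graph joining pairs with d < *t* (single linkage, ABGD-style);
   defaults compare *t* = 3.5% and 4.0%;
5. validates the resulting groups by canonical discriminant analysis on
   principal-coordinate embeddings of the distance matrix (the DAPC
   strategy), classifying each sequence to the nearest group centroid under
   leave-one-out cross-validation;
6. optionally compares per-gene divergences of a multi-gene panel against
   COI with Wilcoxon signed-rank tests and per-gene regressions.

## Worked example

Simulate a 31-species complex at the whitefly study's geometry (212
sequences, within-species divergence ~1.2%, between-species ~15.7%) and run
the full pipeline:

```sh
barcodegap simulate complex --seed 2 --out-prefix sim
barcodegap run sim.fasta --taxonomy sim.tsv --out-dir out --threshold 3.5 --threshold 4.0
```

which prints

```
t=3.5%: 31 clusters
t=4%: 31 clusters
```

meaning both candidate thresholds recover the 31 simulated species for this
draw (a species harbouring within-species divergence above 3.5% would be
oversplit at the lower threshold — see `simulate_deep_split_complex`).
`out/report.json` contains the per-stage summaries; for this run the
within-species average divergence is 1.2% (1839 comparisons), the
between-species average is 15.6% (20527 comparisons), and the
leave-one-out discriminant validation reclassifies 96.7% of sequences into
their own group — the shortfall is exactly the seven singleton groups,
whose only member cannot be classified to a group it was held out of.
`out/level_summaries.tsv`, `out/histogram.tsv` and `out/clusters_t*.tsv`
hold the corresponding tables.

The same steps work on real data: an aligned FASTA plus a taxonomy TSV with
header `id species genus family group` (`barcodegap trim --ref NC_006279
--window 650` first, if the alignment is untrimmed).

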