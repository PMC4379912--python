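# mtphylogeo

A matrilineal-phylogeography toolkit for human mtDNA:

- **Variant notation & calling** — phylotree-style mutation tokens on the
  standard 16,569-bp circular coordinate frame (`16172`, `16183C`,
  `16193.1C`, `8281-8289d`, `@10398`), pairwise variant calling against the
  reference with 3'-most indel placement, functional classification of
  substitutions (synonymous / nonsynonymous / tRNA / rRNA / noncoding /
  control region), the conventional hypermutable-site exclusion filter, and
  in-silico RFLP typing of the six coding-region marker sites.
- **Haplogroup classification** — a rooted clade tree with defining-mutation
  motifs (bundled fixture tree includes M54a, M55b, M84b and relatives),
  cumulative-motif scoring restricted to each sample's sequenced ranges, and
  macro-ancestry summaries.
- **Median-joining networks** — epsilon-relaxed minimum-spanning connectivity
  plus median (Steiner) vector generation, exported as GML or DOT.
- **Rho dating** — the rho statistic and its branch-weighted standard error
  on rooted genealogies (star fallback from variant profiles), with three
  fixed clocks (one mutation per 2,585 / 7,884 / 18,845 years for
  complete-genome, coding-synonymous and HVS-I-transition classes).
- **Population statistics** — haplogroup frequency tables, PCA, the
  Bhattacharyya-type frequency distance, two-level AMOVA with Phi indices
  and permutation tests, and constrained WLS admixture estimation.
- **Spatial autocorrelation** — Moran's I correlograms over great-circle
  distance classes with permutation significance.
- **Synthetic data** — seeded generators for star/bifurcating genealogies,
  clade fixture profiles, and multi-population frequency tables with
  optional geographic clines.

## A note on the bundled reference

The bundled FASTA uses the standard 16,569-bp mtDNA coordinate frame and
the real gene annotation (13 protein genes including light-strand ND6, 22
tRNAs, 2 rRNAs). Its base content is a seeded placeholder with a set of
well-known landmark positions pinned to their true values (poly-C tracts,
the AC repeat, the 9-bp repeat, HVS-I landmarks); sequence-dependent
results are internally consistent but not a substitute for the true
reference. Supply your own via `load_reference(fasta_path=...)` for real
data. `scripts/make_reference_fasta.py` regenerates the bundled file.

## CLI

```sh
mtphylogeo classify cohort.tsv --out assignments.tsv        # or a FASTA
mtphylogeo date clade.tsv --haplogroup M55b --root-tokens "..." \
    --clock complete_genome --out ages.tsv
mtphylogeo network variants.tsv --panel "489 10400 16223" --out net.gml
mtphylogeo stats pops.csv --pca --amova --seed 1234 --out stats.json
mtphylogeo spatial pops.csv --haplogroup H1 --classes 5 --seed 1 --out corr.tsv
mtphylogeo simulate --seed 7 --mode star --n 20 --lam 3 --out sim.tsv
```

Formats: variant tables are TSV (`SampleID`, `Range` such as `16024-407;...`,
`Variants` as space-separated tokens); haplogroup trees are TSV
(`Name`, `Parent`, `Motif`, `Ancestry`); population tables are CSV
(`Population`, `Group`, `Lat`, `Lon`, `n`, one column per haplogroup).

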