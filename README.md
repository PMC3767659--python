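# nestkin

Sociogenetic and population-genetic analysis of colony-structured genotype
tables and mtDNA alignments, with a synthetic-data generator for end-to-end
testing.  The pipeline covers:

- **simulate** — microsatellite locus panels, strictly monogynous colonies
  with polyandrous queens (unequal paternity, queen-son and worker-son males,
  alate females, optional thelytokous clones), nest maps (random / grid /
  clustered) and two-group mtDNA transects with built-in isolation by
  distance.  Every simulated colony carries a hidden-truth sidecar for
  recovery testing.
- **sociogenetics** — queen reconstruction from worker genotypes, exact
  minimum-father patriline partitions, matriline assignment, effective
  paternity (skew-corrected), non-detection probabilities for shared-male and
  worker-son errors, male/female parentage classification, and symmetric
  Queller–Goodnight relatedness with delete-one-colony jackknife errors.
- **popgen** — observed/expected heterozygosity (Nei unbiased), exact
  Hardy–Weinberg and linkage tests under a one-individual-per-colony
  resampling design, Weir & Cockerham F-statistics (jackknife SE + bootstrap
  CI over loci), pairwise theta matrices, Monte-Carlo G tests of pairwise
  differentiation with Fisher combination and Bonferroni correction, and the
  second-order Delta-K summary for clustering likelihood tables.
- **spatial** — Clark & Evans nearest-neighbour index with the Donnelly
  boundary correction, linearised-F_ST vs ln-distance tables, and a
  rank-based (Spearman) Mantel test with seeded permutations.
- **mtdna** — haplotype collapsing, substitution counts and uncorrected
  p-distances, median-joining networks (epsilon = 0), and hierarchical AMOVA
  with permutation p-values.
- **demography** — Yates-corrected chi-square, exact rank-sum and
  Kruskal–Wallis tests, and numerical sex ratios for nest censuses.

## Command-line interface

The `nestkin` entry point mirrors the analysis stages:

```sh
nestkin simulate   --config scenario.yaml --outdir out/
nestkin sociogen   --genotypes out/genotypes.csv --outdir out/ --seed 1
nestkin popgen     --genotypes out/genotypes.csv --outdir out/ --seed 2
nestkin spatial    --coordinates out/coordinates.csv --fst out/pairwise_fst.tsv \
                   --outdir out/ --seed 3
nestkin mtdna      --fasta out/mtdna.fasta --sites out/mtdna_sites.tsv \
                   --outdir out/ --seed 4
nestkin demography --census out/census.csv --outdir out/
nestkin run-all    --config scenario.yaml --outdir out/
```

`run-all` takes a single YAML config; every stochastic stage must declare an
explicit seed and permutation counts of at least 999 (no hidden defaults).
A minimal config:

```yaml
stages: [simulate, sociogen, popgen, spatial, mtdna, demography]
simulate:
  seed: 1
  n_loci: 7
  plot: {side_length: 34.0, n_nests: 20, placement: random, seed: 2}
  colony: {n_workers: 12, contributions: [6, 4, 2]}
  transect: {n_sites: 10, site_spacing: 15.0, seed: 3}
sociogen: {seed: 4, min_workers: 8}
popgen: {seed: 5, replicates: 20, permutations: 10000, alpha: 0.05}
spatial: {seed: 6, permutations: 10000}
mtdna: {seed: 7, permutations: 10000}
```

Reports are written as machine-readable JSON plus per-statistic TSVs; reruns
with the same config are byte-identical.

## File formats

- Genotype CSV: columns `id, colony, caste, ploidy` plus two columns per
  locus (`<locus>.1` / `<locus>.2`); missing allele code 0; haploid males
  carry one call.
- GENEPOP export (diploids only) with deterministic smallest-size-first
  allele recoding; the package's own reader round-trips it.
- FASTA alignments: equal-length, gap-free ACGTN sequences.

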