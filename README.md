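# ylandscape

Analyses for selective sequencing of a single target chromosome — built for
Y-chromosome (chrY) studies where the target is enriched by flow-cytometry
chromosome sorting or by nanopore adaptive sampling, assembled, and profiled
for structural variation and CpG methylation across a panel of haplogroups.

The package implements the downstream computations such a study needs, each
behind a small library surface with a thin CLI, plus a seeded synthetic-data
generator so every stage can be exercised with truth-known inputs:

- **Enrichment** — per-chromosome coverage and enrichment factor, excluding
  assembly gaps (N stretches) and weighting by ploidy:

  ```
  coverage(c) = mapped_bp(c) / size_without_N(c)

  EF(c) = (mapped_bp(c) / total_mapped_bp)
          ─────────────────────────────────────────────
          (size_without_N(c) · ploidy(c) / diploid_size_without_N)
  ```

  EF = 1 means no enrichment. For a target enriched `f`-fold that holds a
  share `w` of the ploidy-weighted non-N genome, the expected factor is
  `f / (w·f + 1 − w)`.

- **Assembly metrics** — span, N50, L50 and sequence counts, plus the
  `keep_percent` needed to base-match two datasets before comparing
  assemblies.

- **Structural variants** — post-caller panel construction for a hemizygous
  chromosome: drop breakpoint-imprecise calls, merge insertions and
  deletions separately by single-linkage clustering of start positions
  (100 bp default), mask genotypes with quality < 25, drop events that are
  reference in every sample, classify sizes into [10,50) / [50,500) /
  [500,∞) bp bins, annotate repeat content, and count carrier-sharing
  patterns across the haplogroup phylogeny.

- **Concordance** — genotypes binarized to presence/absence (any
  alternative call on a hemizygous chromosome implies carrier status),
  pairwise phi coefficients (Matthews correlation,
  `phi = (n11·n00 − n10·n01)/√(n1·n0·n·1·n·0)`) with Fisher-exact or
  chi-square p-values and Bonferroni correction, and population presence
  calling at carrier frequency > 0.2.

- **Methylome** — per-CpG methylation frequency tables (nanopolish-style
  TSV) filtered at ≥ 4x coverage, quantile-normalized across samples,
  annotated by CpG category (island / 2-kb shore / 2-kb shelf / open sea),
  sequence class (PAR, X-degenerate, X-transposed, ampliconic,
  heterochromatic) and gene feature (200-bp TSS region, UTRs, first exon,
  intragenic, upstream), summarized as 250-kb window tracks with a
  cross-sample dispersion channel, per-island means, a scan for
  high-dispersion regions, and a methylome-distance tree (1 − Pearson,
  UPGMA) compared to the haplogroup phylogeny by Robinson–Foulds distance.

## Worked example

Simulate a small male genome (four diploid autosomes plus a haploid,
gap-rich chrY holding ~1% of the ploidy-weighted genome), allocate 10 Mb of
mapped bases with chrY enriched 50-fold, and compute enrichment factors:

```bash
ylandscape simulate genome  --seed 3 --out-dir g
ylandscape simulate mapping --seed 3 --fold 50 --out-dir m
ylandscape enrich --summary m/mapping_summary.tsv --sizes g/sizes.tsv \
    --gaps g/gaps.bed --ploidy g/ploidy.yaml --target chrY --out enrich.tsv
cat enrich.tsv
```

```
sample  target  target_enrichment  autosome_mean       autosome_sd
sim     chrY    33.53211138        0.6708115513690476  0.0005982878466130776
```

The target's factor 33.5 matches the closed form `50/(0.0101·50 + 0.9899)`
for this genome's chrY share, and the autosomes sit at the complementary
`1/(w·f + 1 − w) ≈ 0.67`: enriching one chromosome necessarily depresses
every other chromosome's share. With `--fold 1` every factor is 1.

The same objects are available as a library:

```python
from ylandscape import simulate as sim
from ylandscape import enrichment_factor

syn = sim.make_genome(seed=3)
summary = sim.simulate_mapping(syn.genome, fold=50, total_bases=10**7, seed=3)
result = enrichment_factor(summary, syn.genome, target="chrY")
print(result.target_enrichment)   # 33.53...
```

Other subcommands: `simulate svpanel|methylome|contigs`, `sv-merge`,
`sv-share`, `concord`, `asm-stats`, `methylome-run`. Each writes a JSON run
manifest with its parameters next to its outputs.

## Layout

```
src/ylandscape/
  core_io.py      genome/gap/ploidy definitions, mapping summaries, SV VCF
                  dialect, BED/BED12, newick
  simulate.py     seeded generators: genome+annotations, mapping, SV panels,
                  methylomes, contig lengths
  enrichment.py   coverage and enrichment factors, report and plot
  assembly.py     N50/L50/span, keep_percent
  sv.py           imprecise/quality filters, indel merging, size bins,
                  repeat content, sharing profiles
  concordance.py  binarization, phi, significance, population presence
  methylome.py    filtering, quantile normalization, annotation, tracks,
                  dispersion scan, methylome tree
  cli.py          click entry points
```

See `docs/methods.md` for the models, parameter choices and limitations.
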