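# Methods

This note records the models and procedures the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the choices made where the design was genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open, matching BED. VCF
(1-based) is converted at the I/O boundary (`internal start = POS − 1`) and
back on write; the conversion is a bijection and a write→read round trip
preserves records. Interval containers are normalized (sorted, merged) on
construction; normalization is idempotent.

The SV VCF dialect carries `SVTYPE` (INS/DEL/DUP/TRA, BND read as TRA),
`SVLEN` (sign ignored on read, deletions written negative) or `END`, an
optional `IMPRECISE` flag, and per-sample `GT[:GQ]`. When no `GQ` field is
present the record `QUAL` backs every genotype's quality, so the quality
threshold applies to whichever quality the file actually provides. Records
without `SVTYPE` are rejected with a logged reason.

Methylation frequency tables follow the nanopolish
`calculate_methylation_frequency` dialect (chromosome, start, end,
num_motifs_in_group, called_sites, called_sites_methylated,
methylated_frequency, group_sequence). Coordinates are treated as 0-based,
matching that tool's output; a `one_based` flag converts other dialects at
the boundary. Grouped CpG calls keep their group footprint as one site by
default; `split_groups` replicates the group counts onto each member CpG.

## Enrichment model

For chromosome c with mapped bases m(c), non-N size s(c) and ploidy n(c):

    coverage(c) = m(c) / s(c)
    EF(c) = (m(c) / Σm) / (s(c)·n(c) / Σ s·n)

Gaps are excluded because a reference with long N stretches (over half a
human Y) would otherwise understate coverage; ploidy weighting accounts for
the real target space of haploid chromosomes in a male genome. EF = 1 means
no enrichment, and the identity Σ_c EF(c)·w(c) = 1 (w the ploidy-weighted
non-N share) holds by construction — enrichment of one chromosome must
depress the others' shares. For a target enriched f-fold with share w, the
expected factor is f/(w·f + 1 − w), which is the closed form the simulator
recovery tests check against.

Chromosomes with zero mapped bases are reported with EF 0 rather than
dropped. The autosome mean ± SD excludes sex chromosomes, mitochondria and
underscore-named unplaced contigs; unplaced target contigs can be pooled
into the target (`merge_into_target`), for workflows that enrich a
chromosome together with its unplaced contig. Mapped bases on chromosomes
absent from the genome definition are an error here (the denominator is
undefined) but only a warning in the alignment adapter.

The alignment adapter counts aligned query bases of primary alignments
only, excluding secondary and supplementary records. Whether supplementary
alignments should count is a judgement call — counting them would
double-count split reads — and summaries produced by other tools can be
supplied as TSV instead.

## Assembly metrics

N50 uses the "≥ span/2" convention (the first length at which the
descending cumulative sum reaches at least half the span), the dominant
convention in assembly reporting; L50 is the number of sequences needed to
reach it. Span counts raw sequence lengths including N bases.
`keep_fraction` returns 100·min/max rounded to one decimal and identifies
which dataset to downsample, for base-matching two datasets before
comparing their assemblies.

One caution surfaced by property testing: N50 is *not* monotone under
lengthening an arbitrary sequence (growing a short sequence raises span/2
and can push the threshold across a plateau of equal lengths, lowering
N50); it is monotone under lengthening the longest.

## SV panel construction

Stages, in the order a pipeline applies them:

1. **Imprecise filter** — drop records the caller flagged breakpoint-
   imprecise.
2. **Merge** — insertions and deletions separately, per chromosome, by
   single-linkage clustering of start positions at a maximum distance of
   100 bp (calls 100 bp up- or downstream join one event). Lengths are not
   compared; this is a dialect of SURVIVOR-style merging, not a
   reimplementation of it. The merged record takes the position and length
   of its first member in position order (determinism); per-sample
   genotypes come from each sample's own member, missing when a sample
   contributed none. When two members of one sample disagree, the
   higher-quality genotype wins and the conflict is logged. DUP/TRA records
   pass through unmerged and are excluded from size bins.
3. **Genotype filter** — genotypes with quality under 25 become missing
   ("under" is strict: 24.9 masked, 25.0 kept); events homozygous reference
   or missing in every sample are dropped.
4. **Size bins** — [10,50), [50,500), [500,∞) bp; events under the 10-bp
   panel floor are rejected (the floor mirrors common caller/comparison
   settings for indel panels).
5. **Repeat content** — fraction of the variant footprint
   [start, start+length) covered by a repeat annotation, with the dominant
   repeat class (ties broken lexicographically). The reference footprint is
   used for insertions too: annotating the inserted sequence itself would
   require sequence content, which this package does not model.
6. **Sharing profiles** — over variants genotyped in *all* samples,
   counts of each carrier pattern (singletons per sample, shared-by-all,
   intermediates), suitable for upset-style plots against the phylogeny.

Merging is idempotent, and the merged event count is non-increasing in the
maximum distance (single linkage at a smaller distance refines the
clustering at a larger one); both are tested on random panels.

## Concordance

Binarization maps hom/het alternative calls to present and hom-reference
to absent — on a hemizygous chromosome any alternative call implies carrier
status — with missing preserved. Phi is computed from the 2×2 table over
pairwise-complete entries; it equals the Pearson correlation of the 0/1
vectors, and n·phi² equals the chi-square statistic, both used as test
oracles. A zero margin makes phi undefined; it is reported as missing with
a reason, never as 0.

Significance per pair is Fisher's exact test by default (robust for the
small, sparse tables hemizygous panels produce), with the chi-square of
n·phi² (df 1) as an option; the source study names neither procedure, so
both are exposed. Bonferroni uses m = the number of pairs actually tested
(those with a defined coefficient) — the most conservative defensible
family for the matrix actually reported. Population presence calls a
variant present in a group iff its carrier frequency among genotyped
individuals is strictly greater than 0.2; a group with nobody genotyped is
missing.

## Methylome pipeline

Order of operations: coverage filter (≥ 4x per sample) and
alternative-allele mask → complete-case matrix (sites passing in **all**
samples) → quantile normalization → annotation → summaries. Complete cases
are required because the quantile-normalization target is undefined with
missing entries; a per-sample rank-against-pooled-reference variant would
relax this but is not the default.

Quantile normalization replaces each column's values by the across-sample
mean of order statistics at their rank; tied values receive the mean of
their tied ranks' values. With ties this deliberately sacrifices the exact
sorted-multiset identity (the two properties are incompatible); on
continuous data ties have measure zero. Normalized values are clamped to
[0,1] (they can exit only by rounding).

CpG categories form a partition with priority island > shore > shelf >
open sea: shores are the 2-kb bands beyond island edges, shelves the next
2 kb, open sea the remainder. Gene features use the annotation priority
promoter/TSS > 5′UTR > 3′UTR > first exon > other exons > introns >
upstream, strand-aware; the TSS region is exactly the 200 bp upstream of
the transcription start, and "upstream" is defined here as the next 2 kb
beyond it (the priority list's last entry has no standard extent; 2 kb
matches the shore/shelf length scale). Non-first exons and introns are
reported collapsed as "intragenic". Every site receives exactly one value
per annotation axis; the partitions are tested by exhaustive sampling.

Window tracks default to non-overlapping 250-kb tiles anchored at 0
(a configurable step allows sliding windows; tiling keeps the dispersion
channel's windows independent): per window, each sample's median
normalized frequency, and across samples the SD of those medians (sample
SD, missing with < 2 medians). Windows use normalized frequencies by
default; raw frequencies are available by passing the unnormalized matrix.

The dispersion scan ranks windows by cross-sample SD, keeps the top 10
that also exceed an SD z-score of 3 over the track, merges adjacent
windows, and reports overlapping genes, per-sample medians and the most
deviating sample. The defaults suit a landscape expected to contain at
most a handful of genuine sample-specific regions; with fewer than ~15
informative windows the z ≥ 3 filter cannot trigger and the scan correctly
returns nothing.

The methylome tree uses 1 − Pearson distance between sample columns
(Euclidean on window medians as an option) and UPGMA linkage, compared to
a reference phylogeny by unrooted Robinson–Foulds distance. These are
package choices, not established facts about methylome data: UPGMA assumes
an ultrametric signal, and RF = 0 is reported as "topology recovered", any
other value as the degree of disagreement.

## Synthetic data

Generators share one global seed fanned out to fixed per-stage streams, so
re-running one stage alone reproduces its output. Identical configuration
and seed give identical outputs.

**Genome.** Four diploid autosomes (26 Mb total, 5% gaps) and a haploid
1-Mb target holding ~1% of the ploidy-weighted non-N genome — the share a
human Y holds of a male genome. Sequence classes tile the target in the
order PAR (5%), X-degenerate (16%), X-transposed (6%), ampliconic (18%),
heterochromatic (55%), and the target's N stretches (50% of its length by
default) are placed inside the heterochromatic segment, as on a real Y
where the q-arm heterochromatin holds the unresolved sequence. CpG islands
(30 × 1 kb), repeats and BED12 gene models are placed outside gaps.

**Mapping.** Bases are allocated multinomially with probability
proportional to ploidy-weighted non-N size, the target's probability
multiplied by the enrichment fold — a single-parameter caricature of
selective sequencing that reproduces the closed-form expected EF but none
of read-length, mappability or co-sorting structure (so the co-enrichment
of similarly sized chromosomes seen in real sorted data is absent by
construction).

**SV panels.** Each variant lands on a uniformly chosen branch of the
sample phylogeny and all leaves below carry the hemizygous alternative
genotype — branch-uniform placement is a stand-in, not a population-
genetic model. A second platform observes the same variants with
presence/absence flips at a configurable rate; missing genotypes are
injected independently into both panels. Platform noise is genotype-level,
not read-level, because the concordance analysis consumes genotypes only.

**Methylomes.** Each site draws a true frequency from a beta distribution
whose mean/concentration depend on its CpG category (island 0.10/12,
shore 0.35/8, shelf 0.50/8, open sea 0.679/6, X-degenerate open sea
0.724/6). The open-sea means are calibrated so the implied beta *medians*
sit at the landmark medians of real chrY data (0.70 genome-wide, 0.75 in
the X-degenerate class); for a left-skewed beta the median exceeds the
mean, so naively setting mean = landmark would overshoot the median by
~0.05. Coverage is Poisson per site and sample, observed methylated counts
binomial. An optional planted region shifts one sample's true frequencies
by δ (clipped to [0,1]); an optional phylogeny adds per-branch Gaussian
offsets on the logit scale accumulated root-to-leaf, variance proportional
to branch length. The default tree is ultrametric (UPGMA's assumption) with
the two basal lineages sister to the rest. Not emulated: read-level error,
bimodality beyond what the beta produces, spatial autocorrelation along the
chromosome, and any linkage between SVs and methylation — so passing tests
demonstrate the pipeline's arithmetic and recovery behavior, not
performance on real nanopore data.

## Problem sizes

Tests and the acceptance script run at desk scale by design: genomes of
tens of megabases, 10⁷-base multinomials over 200 replicates for
enrichment recovery, SV panels of a few hundred variants, methylomes of
15–20 thousand CpG sites over 5-Mb chromosomes with 50 seeds for the
planted-region power check, and 20 seeds for topology recovery. These
sizes give Monte-Carlo error comfortably inside the asserted tolerances
while the full suite runs in well under a minute.

## Known limitations

- The merge step clusters on start positions only; two same-type events of
  very different lengths 100 bp apart will merge. Matching lengths would
  need a reciprocal-overlap criterion, which the positional-distance
  semantics deliberately does not include.
- Fisher's exact test is conservative; the Bonferroni-masked matrix
  understates significance relative to the chi-square option.
- The dispersion scan's z-score uses the global SD distribution of the
  track; a chromosome-wide shift in dispersion would mask local regions.
- The methylome tree is a descriptive clustering; no support values or
  uncertainty are attached to the reported RF distance.
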