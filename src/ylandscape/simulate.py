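"""Seeded synthetic data with the statistical structure the analyses assume.

Every generator is deterministic for a fixed seed: one global seed fans out
to independent per-stage streams so a stage re-run alone reproduces its
output. The generators emulate, at desk scale, the data a Y-chromosome
selective-sequencing study produces: a male genome with a gap-rich,
ploidy-1 target chromosome carrying sequence-class / CpG-island / repeat /
gene annotations; multinomial read-base allocation with a fold-enriched
target; phylogeny-structured hemizygous SV genotype panels observed on two
noisy platforms; and per-CpG methylation tables with category-dependent
structure (islands low, open sea high), binomial coverage sampling and an
optional planted sample-specific hypomethylated region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .core_io import GeneModel, GenomeDef, HaplogroupTree, MappingSummary
from .intervals import Interval, IntervalIndex
from .sv import HOM_ALT, HOM_REF, MISSING, SVPanel, SVRecord

_STAGES = {"genome": 0, "mapping": 1, "svpanel": 2, "methylome": 3, "contigs": 4}

#: MSY-like sequence classes and the fraction of the target chromosome each
#: tiles (mutually exclusive, exhaustive; heterochromatin last and largest,
#: as on a real Y where the q-arm heterochromatin holds the N stretches)
DEFAULT_CLASS_FRACTIONS = {
    "PAR": 0.05,
    "X-degenerate": 0.16,
    "X-transposed": 0.06,
    "ampliconic": 0.18,
    "heterochromatic": 0.55,
}

#: per-CpG-category mean / concentration of the beta distribution of true
#: methylation frequencies; islands unmethylated, open sea methylated. The
#: open-sea means are calibrated so the implied beta *medians* sit at the
#: landmark medians of real data (0.70 genome-wide, 0.75 in the
#: X-degenerate class); for a left-skewed beta the median exceeds the mean.
DEFAULT_CATEGORY_PARAMS: dict = {
    "island": (0.10, 12.0),
    "shore": (0.35, 8.0),
    "shelf": (0.50, 8.0),
    "open_sea": (0.679, 6.0),
    ("X-degenerate", "open_sea"): (0.724, 6.0),
}

#: ultrametric haplogroup phylogeny used as the default sample tree: seven
#: major Y haplogroups with the two basal African lineages sister to the
#: rest, branch lengths loosely in units of 10 kyr
DEFAULT_TREE_NEWICK = (
    "((A0:5,A1a:5):20,((C:8,(H:4,J:4):4):8,(R1b:10,O2a:10):6):9);"
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


def default_tree() -> HaplogroupTree:
    return HaplogroupTree.from_newick(DEFAULT_TREE_NEWICK)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Layout of the synthetic genome.

    Defaults make a small male genome: four diploid autosomes and a
    haploid, gap-rich target chromosome holding about 1% of the
    ploidy-weighted non-N genome, mirroring the share a Y chromosome holds
    of a real genome.
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 8_000_000),
            ("chr2", 7_000_000),
            ("chr3", 6_000_000),
            ("chr4", 5_000_000),
            ("chrY", 1_000_000),
        ]
    )
    target: str = "chrY"
    gap_fraction: dict[str, float] = field(default_factory=lambda: {"chrY": 0.5})
    default_gap_fraction: float = 0.05
    ploidy: dict[str, int] = field(default_factory=lambda: {"chrY": 1})
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    n_cgi: int = 30
    cgi_length: int = 1000
    n_repeats: int = 60
    n_genes: int = 8


@dataclass
class SyntheticGenome:
    genome: GenomeDef
    classes: list[Interval]
    cgi: list[Interval]
    repeats: list[Interval]
    genes: list[GeneModel]


def make_genome(spec: Optional[GenomeSpec] = None, seed: int = 0) -> SyntheticGenome:
    """Deterministic genome + annotations; sequence classes tile the target
    chromosome, mutually exclusive and exhaustive."""
    spec = spec or GenomeSpec()
    rng = stage_rng(seed, "genome")
    for name, length in spec.chromosomes:
        if length < 10_000:
            raise ValueError(f"chromosome {name}: length must be >= 10 kb")
    if abs(sum(spec.class_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("sequence-class fractions must sum to 1")

    target_len = dict(spec.chromosomes)[spec.target]
    classes: list[Interval] = []
    pos = 0
    items = list(spec.class_fractions.items())
    for i, (cls, frac) in enumerate(items):
        end = target_len if i == len(items) - 1 else pos + int(round(frac * target_len))
        if end > pos:
            classes.append(Interval(spec.target, pos, end, name=cls))
        pos = end
    hetero = next((c for c in classes if c.name == "heterochromatic"), None)

    gaps: dict[str, list[tuple[int, int]]] = {}
    for name, length in spec.chromosomes:
        frac = spec.gap_fraction.get(name, spec.default_gap_fraction)
        gap_total = int(round(frac * length))
        if gap_total <= 0:
            continue
        # on the target, N stretches live inside the heterochromatic class
        # (as on a real Y); overflow and other chromosomes get random gaps
        placed: list[tuple[int, int]] = []
        if name == spec.target and hetero is not None:
            in_hetero = min(gap_total, len(hetero))
            s = hetero.start + (len(hetero) - in_hetero) // 2
            placed.append((s, s + in_hetero))
            gap_total -= in_hetero
        if gap_total > 0:
            free = length - sum(e - s for s, e in placed)
            n_gaps = min(3, max(1, gap_total // 10_000))
            cuts = np.sort(rng.integers(0, max(free - gap_total, 1), size=n_gaps))
            sizes = rng.multinomial(gap_total, np.full(n_gaps, 1.0 / n_gaps))
            offset = 0
            for cut, size in zip(cuts, sizes):
                if size == 0:
                    continue
                s = int(cut) + offset
                placed.append((s, s + int(size)))
                offset += int(size)
        gaps[name] = iv.clip(iv.normalize(placed), 0, length)

    genome = GenomeDef(list(spec.chromosomes), gaps, dict(spec.ploidy))

    gap_idx = IntervalIndex(genome.gaps.get(spec.target, []))
    cgi: list[Interval] = []
    occupied: list[tuple[int, int]] = []
    tries = 0
    while len(cgi) < spec.n_cgi and tries < spec.n_cgi * 50:
        tries += 1
        s = int(rng.integers(0, max(target_len - spec.cgi_length, 1)))
        e = s + spec.cgi_length
        if gap_idx.contains(np.array([s, e - 1])).any():
            continue
        if any(s < oe and e > os_ for os_, oe in occupied):
            continue
        occupied.append((s, e))
        cgi.append(Interval(spec.target, s, e, name=f"CGI_{len(cgi) + 1}"))
    cgi.sort(key=lambda c: c.start)
    cgi = [Interval(c.chrom, c.start, c.end, name=f"CGI_{i + 1}") for i, c in enumerate(cgi)]

    repeat_classes = ["AluY", "L1HS", "LTR12B", "Simple_repeat"]
    repeats = []
    for _ in range(spec.n_repeats):
        s = int(rng.integers(0, max(target_len - 5000, 1)))
        ln = int(rng.integers(150, 5000))
        repeats.append(
            Interval(spec.target, s, min(s + ln, target_len),
                     name=repeat_classes[int(rng.integers(len(repeat_classes)))])
        )
    repeats.sort(key=lambda r: (r.start, r.end))

    genes: list[GeneModel] = []
    gene_span = max(target_len // (spec.n_genes * 2), 5000)
    for k in range(spec.n_genes):
        g_start = int(rng.integers(3000, max(target_len - gene_span - 1, 3001)))
        n_exons = int(rng.integers(2, 6))
        exon_starts = np.sort(rng.choice(np.arange(0, gene_span - 400, 400),
                                         size=n_exons, replace=False))
        exons = [(g_start + int(s), g_start + int(s) + int(rng.integers(100, 400)))
                 for s in exon_starts]
        exons = iv.normalize(exons)
        g_end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        thick_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        thick_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        genes.append(
            GeneModel(
                chrom=spec.target, start=exons[0][0], end=g_end,
                name=f"GENE_{k + 1}", strand=strand, exons=exons,
                thick_start=thick_start, thick_end=max(thick_end, thick_start + 1),
            )
        )
    genes.sort(key=lambda g: g.start)

    return SyntheticGenome(genome=genome, classes=classes, cgi=cgi,
                           repeats=repeats, genes=genes)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def simulate_mapping(genome: GenomeDef, fold: float, total_bases: int,
                     seed: int = 0, target: str = "chrY",
                     sample: str = "sim") -> MappingSummary:
    """Allocate mapped bases multinomially with probability proportional to
    ploidy-weighted non-N size, the target's probability multiplied by
    ``fold``. The expected enrichment factor of the target is
    fold / (w*fold + 1 - w) with w the target's share of the diploid non-N
    genome."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    rng = stage_rng(seed, "mapping")
    weights = np.array(
        [genome.non_n_size(c) * genome.chrom_ploidy(c) for c in genome.names], dtype=float
    )
    weights[genome.names.index(target)] *= fold
    probs = weights / weights.sum()
    counts = rng.multinomial(total_bases, probs)
    return MappingSummary(
        sample=sample,
        mapped_bases={c: int(n) for c, n in zip(genome.names, counts)},
    )


# ---------------------------------------------------------------------------
# SV panels
# ---------------------------------------------------------------------------

@dataclass
class SVTruth:
    """Ground truth for a simulated SV panel pair."""

    branch_leaves: list[frozenset[str]]       # carrier set per variant
    genotype_matrix: pd.DataFrame             # variants x samples, 1 = carrier
    samples: list[str]


def simulate_sv_panel(
    tree: Optional[HaplogroupTree] = None,
    n_variants: int = 200,
    platform_error: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "chrY",
    chrom_length: int = 1_000_000,
) -> tuple[SVPanel, SVPanel, SVTruth]:
    """Phylogeny-structured hemizygous SV genotypes on two platforms.

    Each variant lands on a uniformly chosen branch of the tree; every leaf
    below it carries the (hemizygous) alternative genotype. The first panel
    reports the true genotypes; the second perturbs them with
    presence/absence flips at ``platform_error``. Missing genotypes are
    injected independently into both panels at ``missing_rate``.
    """
    import logging

    if not 0 <= platform_error <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    tree = tree or default_tree()
    samples = tree.leaf_names
    rng = stage_rng(seed, "svpanel")
    if n_variants == 0:
        logging.getLogger(__name__).warning("simulate_sv_panel: n_variants = 0")
        empty = pd.DataFrame(columns=samples)
        return (
            SVPanel([], list(samples), "ont"),
            SVPanel([], list(samples), "illumina"),
            SVTruth([], empty, list(samples)),
        )

    # branches: one per non-root node (the edge above it); the root's own
    # edge places a variant shared by every leaf
    nodes = list(tree.tree.preorder_node_iter())
    branch_sets = [
        frozenset(lf.taxon.label for lf in node.leaf_iter()) for node in nodes
    ]
    choice = rng.integers(0, len(branch_sets), size=n_variants)
    starts = np.sort(rng.integers(0, chrom_length, size=n_variants))
    lengths = np.round(10 ** rng.uniform(1.0, 3.8, size=n_variants)).astype(int)
    types = np.where(rng.random(n_variants) < 0.4, "INS", "DEL")

    truth_rows = []
    ont_records, ilm_records = [], []
    carriers_per_variant: list[frozenset[str]] = []
    for i in range(n_variants):
        carriers = branch_sets[int(choice[i])]
        carriers_per_variant.append(carriers)
        truth_rows.append([1.0 if s in carriers else 0.0 for s in samples])
        true_gt = {s: (HOM_ALT if s in carriers else HOM_REF) for s in samples}

        def observe(flip_rate: float) -> dict[str, str]:
            gts = {}
            for s in samples:
                gt = true_gt[s]
                if flip_rate > 0 and rng.random() < flip_rate:
                    gt = HOM_REF if gt == HOM_ALT else HOM_ALT
                if missing_rate > 0 and rng.random() < missing_rate:
                    gt = MISSING
                gts[s] = gt
            return gts

        common = dict(
            chrom=chrom,
            start=int(starts[i]),
            svtype=str(types[i]),
            length=int(max(lengths[i], 10)),
            precise=True,
        )
        quals = {s: 60.0 for s in samples}
        ont_records.append(
            SVRecord(genotypes=observe(0.0), qualities=dict(quals),
                     record_id=f"sv{i + 1}", **common)
        )
        ilm_records.append(
            SVRecord(genotypes=observe(platform_error), qualities=dict(quals),
                     record_id=f"sv{i + 1}", **common)
        )

    truth = SVTruth(
        branch_leaves=carriers_per_variant,
        genotype_matrix=pd.DataFrame(
            truth_rows, columns=samples, index=[f"sv{i + 1}" for i in range(n_variants)]
        ),
        samples=list(samples),
    )
    return (
        SVPanel(ont_records, list(samples), "ont"),
        SVPanel(ilm_records, list(samples), "illumina"),
        truth,
    )


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

@dataclass
class PlantedRegion:
    """A sample-specific methylation shift over one interval."""

    region: Interval
    sample: str
    delta: float  # shift of the true frequency in [-1, 1]

    def __post_init__(self) -> None:
        if not -1 <= self.delta <= 1:
            raise ValueError("delta must be in [-1, 1]")


@dataclass
class MethylomeTruth:
    category_params: dict
    planted: Optional[PlantedRegion]
    site_categories: pd.Series
    site_classes: pd.Series
    tree: Optional[HaplogroupTree]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylome(
    syn: SyntheticGenome,
    n_samples: int = 7,
    n_sites: int = 20_000,
    category_params: Optional[dict] = None,
    planted_region: Optional[PlantedRegion] = None,
    coverage_mean: float = 10.0,
    seed: int = 0,
    sample_names: Optional[Sequence[str]] = None,
    tree: Optional[HaplogroupTree] = None,
    branch_scale: float = 0.0,
) -> tuple[dict[str, pd.DataFrame], MethylomeTruth]:
    """Per-sample methylation frequency tables over shared CpG sites.

    Each site draws a true frequency from a beta distribution whose mean and
    concentration depend on its CpG category (and optionally its sequence
    class); the planted region shifts the affected sample's true frequency
    by delta; per-site per-sample coverage is Poisson around
    ``coverage_mean`` and the observed methylated count binomial. With a
    ``tree`` and ``branch_scale`` > 0, per-branch Gaussian offsets on the
    logit scale accumulate root-to-leaf, giving the samples a
    phylogenetically structured signal.
    """
    from .methylome import annotate_cpg_category, annotate_sequence_class

    params = dict(DEFAULT_CATEGORY_PARAMS)
    if category_params:
        params.update(category_params)
    rng = stage_rng(seed, "methylome")
    genome = syn.genome
    target = syn.classes[0].chrom if syn.classes else genome.names[-1]
    if planted_region is not None:
        pr = planted_region.region
        if pr.chrom not in genome.names or pr.end > genome.length(pr.chrom):
            raise ValueError("planted region outside the genome")

    if tree is not None:
        sample_names = tree.leaf_names
        n_samples = len(sample_names)
    elif sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(n_samples)]
    else:
        n_samples = len(sample_names)

    length = genome.length(target)
    gap_idx = IntervalIndex(genome.gaps.get(target, []))
    positions = np.unique(rng.integers(0, length, size=int(n_sites * 1.6)))
    positions = positions[~gap_idx.contains(positions)][:n_sites]

    pos_df = pd.DataFrame({"chrom": target, "start": positions})
    categories = annotate_cpg_category(pos_df, syn.cgi).to_numpy()
    classes = annotate_sequence_class(pos_df, syn.classes).to_numpy()

    means = np.empty(len(positions))
    conc = np.empty(len(positions))
    for i, (cat, cls) in enumerate(zip(categories, classes)):
        m, k = params.get((cls, cat), params[cat])
        means[i], conc[i] = m, k
    a = np.clip(means * conc, 1e-3, None)
    b = np.clip((1 - means) * conc, 1e-3, None)
    base = rng.beta(a, b)

    # phylogenetic structure: accumulate per-branch logit offsets
    offsets = np.zeros((n_samples, len(positions)))
    if tree is not None and branch_scale > 0:
        sample_index = {s: i for i, s in enumerate(sample_names)}
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            bl = node.edge.length if node.edge.length else 1.0
            eff = rng.normal(0.0, branch_scale * np.sqrt(bl), size=len(positions))
            for lf in node.leaf_iter():
                offsets[sample_index[lf.taxon.label]] += eff

    tables: dict[str, pd.DataFrame] = {}
    for si, s in enumerate(sample_names):
        p = base.copy()
        if branch_scale > 0 and tree is not None:
            p = _expit(_logit(p) + offsets[si])
        if planted_region is not None and s == planted_region.sample:
            pr = planted_region.region
            inside = (pos_df["chrom"] == pr.chrom).to_numpy() & (
                (positions >= pr.start) & (positions < pr.end)
            )
            p = np.where(inside, np.clip(p + planted_region.delta, 0.0, 1.0), p)
        coverage = rng.poisson(coverage_mean, size=len(positions))
        methylated = rng.binomial(coverage, p)
        keep = coverage > 0
        tables[s] = pd.DataFrame(
            {
                "chrom": target,
                "start": positions[keep],
                "end": positions[keep] + 1,
                "n_motifs": 1,
                "called": coverage[keep],
                "methylated": methylated[keep],
                "frequency": methylated[keep] / coverage[keep],
            }
        )

    truth = MethylomeTruth(
        category_params=params,
        planted=planted_region,
        site_categories=pd.Series(categories, index=positions),
        site_classes=pd.Series(classes, index=positions),
        tree=tree,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Contigs
# ---------------------------------------------------------------------------

def simulate_contigs(n: int, mean_log: float = 12.0, sigma: float = 1.0,
                     seed: int = 0) -> list[int]:
    """Heavy-tailed (lognormal) contig lengths for contiguity-metric tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stage_rng(seed, "contigs")
    lengths = np.maximum(rng.lognormal(mean_log, sigma, size=n).astype(np.int64), 1)
    return [int(x) for x in lengths]
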