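"""CpG methylation landscape pipeline.

Ingests per-site methylation frequency tables (nanopolish-style TSV of
called/methylated read counts per CpG group), filters sites by coverage and
an optional alternative-allele mask, quantile-normalizes frequencies across
samples, annotates each site with a CpG category (island / shore / shelf /
open sea), a sequence class and a gene feature, and derives the landscape
summaries: per-class/per-category medians, fixed-width window tracks with
a cross-sample dispersion channel, per-island means, a scan for
high-dispersion regions, and a methylome-distance tree compared against a
reference phylogeny.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import intervals as iv
from .core_io import FEATURE_PRIORITY, GeneModel, GenomeDef, HaplogroupTree
from .intervals import Interval, IntervalIndex

logger = logging.getLogger(__name__)

CPG_CATEGORIES = ("island", "shore", "shelf", "open_sea")
#: width of the shore band beyond an island edge, and of the shelf band
#: beyond a shore edge
SHORE_WIDTH = 2000
SHELF_WIDTH = 2000

GENE_FEATURES = ("tss", "utr5", "utr3", "first_exon", "intragenic", "upstream", "intergenic")

_FREQ_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "num_motifs_in_group",
    "called_sites",
    "called_sites_methylated",
    "methylated_frequency",
    "group_sequence",
]


# ---------------------------------------------------------------------------
# Ingest and filtering
# ---------------------------------------------------------------------------

def load_frequency_table(path, one_based: bool = False,
                         split_groups: bool = False) -> pd.DataFrame:
    """Read a methylation frequency TSV (nanopolish dialect).

    Returns a frame with columns chrom, start, end, n_motifs, called,
    methylated, frequency; coordinates are converted to the 0-based
    convention when ``one_based`` is set. Rows with methylated > called are
    rejected with a logged line number. With ``split_groups`` a grouped call
    covering k CpGs is replicated to one row per CpG (same counts); the
    default keeps the group footprint as a single site.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_FREQ_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.rename(
        columns={
            "chromosome": "chrom",
            "num_motifs_in_group": "n_motifs",
            "called_sites": "called",
            "called_sites_methylated": "methylated",
            "methylated_frequency": "frequency",
        }
    )
    bad = df["methylated"] > df["called"]
    if bad.any():
        for line in (df.index[bad] + 2).tolist():
            logger.warning("%s: line %d rejected (methylated > called)", path, line)
        df = df[~bad]
    df = df.copy()
    if one_based:
        df["start"] = df["start"] - 1
    df["frequency"] = df["methylated"] / df["called"].where(df["called"] > 0)
    if split_groups and (df["n_motifs"] > 1).any() and "group_sequence" in df.columns:
        rows = []
        for rec in df.itertuples(index=False):
            if rec.n_motifs <= 1 or not isinstance(rec.group_sequence, str):
                rows.append(rec._asdict())
                continue
            offsets = [i for i in range(len(rec.group_sequence) - 1)
                       if rec.group_sequence[i : i + 2] == "CG"]
            base = rec.start - offsets[0] if offsets else rec.start
            for off in offsets or [0]:
                d = rec._asdict()
                d["start"] = base + off
                d["end"] = base + off + 1
                d["n_motifs"] = 1
                rows.append(d)
        df = pd.DataFrame(rows)
    keep = ["chrom", "start", "end", "n_motifs", "called", "methylated", "frequency"]
    return df[keep].reset_index(drop=True)


def write_frequency_table(df: pd.DataFrame, path) -> None:
    """Inverse of load_frequency_table (0-based coordinates, no group
    sequence column round-trip)."""
    out = df.rename(
        columns={
            "chrom": "chromosome",
            "n_motifs": "num_motifs_in_group",
            "called": "called_sites",
            "methylated": "called_sites_methylated",
            "frequency": "methylated_frequency",
        }
    )
    out["group_sequence"] = "."
    out.to_csv(path, sep="\t", index=False)


def filter_sites(df: pd.DataFrame, min_coverage: int = 4,
                 alt_allele_mask: Optional[Iterable[Interval]] = None) -> pd.DataFrame:
    """Drop sites below the minimum coverage and sites overlapping the
    alternative-allele mask (positions where an alternative allele replaces
    the reference cytosine, uninformative for 5mC)."""
    keep = df["called"] >= min_coverage
    if alt_allele_mask is not None:
        mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for m in alt_allele_mask:
            mask_by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        for chrom, ivs in mask_by_chrom.items():
            idx = IntervalIndex(ivs)
            rows = df["chrom"] == chrom
            keep &= ~(rows & pd.Series(idx.contains(df["start"].to_numpy()), index=df.index))
    return df[keep].reset_index(drop=True)


def build_matrix(tables: dict[str, pd.DataFrame], min_coverage: int = 4,
                 alt_allele_mask: Optional[Iterable[Interval]] = None) -> pd.DataFrame:
    """Site x sample frequency matrix over complete cases: sites passing the
    coverage filter in *all* samples (the normalization target is undefined
    with missing entries). Index is a (chrom, start) MultiIndex."""
    cols = {}
    for sample, df in tables.items():
        filt = filter_sites(df, min_coverage=min_coverage, alt_allele_mask=alt_allele_mask)
        s = filt.set_index(["chrom", "start"])["frequency"]
        s = s[~s.index.duplicated()]
        cols[sample] = s
    mat = pd.DataFrame(cols).dropna(axis=0, how="any").sort_index()
    return mat


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    Each column's values are replaced by the across-sample mean of order
    statistics at their rank; tied values receive the mean of their tied
    ranks' values, so after normalization every column holds the identical
    sorted multiset. Values are clamped to [0, 1] afterwards (they can exit
    only by floating-point rounding).
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: fewer than 2 samples, returning input")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    order_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(order_means)
        ranked[order] = order_means
        # ties: average the assigned order-statistic means within tied groups
        s = pd.Series(ranked)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def cpg_category_regions(cgi: Sequence[Interval], chrom: str) -> dict[str, list[tuple[int, int]]]:
    """Island/shore/shelf regions for one chromosome, priority-resolved.

    Shores are the 2 kb bands beyond island edges minus islands; shelves the
    next 2 kb minus islands and shores. Everything else is open sea.
    """
    islands = iv.normalize([(c.start, c.end) for c in cgi if c.chrom == chrom]) if cgi else []
    if not islands:
        return {"island": [], "shore": [], "shelf": []}
    shores = iv.subtract(iv.expand(islands, SHORE_WIDTH), islands)
    shelves = iv.subtract(
        iv.subtract(iv.expand(islands, SHORE_WIDTH + SHELF_WIDTH), iv.expand(islands, SHORE_WIDTH)),
        islands,
    )
    return {"island": islands, "shore": shores, "shelf": shelves}


def annotate_cpg_category(positions: pd.DataFrame | pd.MultiIndex,
                          cgi: Sequence[Interval]) -> pd.Series:
    """CpG category per site: island > shore > shelf > open sea."""
    chroms, starts = _positions(positions)
    cat = np.full(len(starts), "open_sea", dtype=object)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        regions = cpg_category_regions(cgi, chrom)
        pts = starts[sel]
        assigned = np.full(pts.shape, "open_sea", dtype=object)
        for name in ("shelf", "shore", "island"):  # low to high priority
            if regions[name]:
                hit = IntervalIndex(regions[name]).contains(pts)
                assigned[hit] = name
        cat[sel] = assigned
    return pd.Series(cat, index=_index(positions), name="cpg_category")


def annotate_sequence_class(positions, classes: Sequence[Interval],
                            default: str = "other") -> pd.Series:
    """Sequence class (PAR / X-degenerate / ... ) per site."""
    chroms, starts = _positions(positions)
    out = np.full(len(starts), default, dtype=object)
    by_chrom: dict[str, list[Interval]] = {}
    for c in classes:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, ivs in by_chrom.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        # abutting class intervals must stay distinct: assign by searchsorted
        # on the sorted starts without merging
        ivs = sorted(ivs, key=lambda c: (c.start, c.end))
        cls_starts = np.array([c.start for c in ivs], dtype=np.int64)
        cls_ends = np.array([c.end for c in ivs], dtype=np.int64)
        names = np.array([c.name or default for c in ivs], dtype=object)
        pts = starts[sel]
        hit = np.searchsorted(cls_starts, pts, side="right") - 1
        ok = (hit >= 0) & (pts < cls_ends[np.clip(hit, 0, None)])
        vals = out[sel]
        vals[ok] = names[hit[ok]]
        out[sel] = vals
    return pd.Series(out, index=_index(positions), name="sequence_class")


_COLLAPSE = {"exon": "intragenic", "intron": "intragenic"}


def annotate_gene_feature(positions, genes: Sequence[GeneModel]) -> pd.Series:
    """Highest-priority overlapping gene feature per site.

    Priority follows the annotation convention promoter/TSS > 5'UTR > 3'UTR
    > first exon > non-first exons > introns > upstream; non-first exons and
    introns are reported collapsed as "intragenic"; sites overlapping no
    gene are intergenic.
    """
    chroms, starts = _positions(positions)
    rank = {f: i for i, f in enumerate(FEATURE_PRIORITY)}
    best = np.full(len(starts), len(FEATURE_PRIORITY), dtype=int)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        pts = starts[sel]
        per_feature: dict[str, list[tuple[int, int]]] = {f: [] for f in FEATURE_PRIORITY}
        for g in gs:
            for f, ivs in g.features().items():
                per_feature[f].extend(ivs)
        for f in FEATURE_PRIORITY:
            if not per_feature[f]:
                continue
            hit = IntervalIndex(per_feature[f]).contains(pts)
            improve = hit & (rank[f] < best[sel])
            best[sel[improve]] = rank[f]
    labels = np.array(
        [_COLLAPSE.get(f, f) for f in FEATURE_PRIORITY] + ["intergenic"], dtype=object
    )
    return pd.Series(labels[best], index=_index(positions), name="gene_feature")


def _positions(positions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(positions, pd.DataFrame):
        return positions["chrom"].to_numpy(dtype=object), positions["start"].to_numpy(np.int64)
    if isinstance(positions, pd.MultiIndex):
        return (
            positions.get_level_values(0).to_numpy(dtype=object),
            positions.get_level_values(1).to_numpy(np.int64),
        )
    raise TypeError("positions must be a DataFrame with chrom/start or a MultiIndex")


def _index(positions):
    if isinstance(positions, pd.DataFrame):
        return positions.index
    return positions


@dataclass
class AnnotatedMethylome:
    """Normalized site x sample matrix plus per-site annotations."""

    matrix: pd.DataFrame           # (chrom, start) x sample, normalized frequencies
    annotations: pd.DataFrame      # cpg_category, sequence_class, gene_feature per site

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)


def annotate_methylome(matrix: pd.DataFrame, cgi: Sequence[Interval] = (),
                       classes: Sequence[Interval] = (),
                       genes: Sequence[GeneModel] = ()) -> AnnotatedMethylome:
    ann = pd.DataFrame(index=matrix.index)
    ann["cpg_category"] = annotate_cpg_category(matrix.index, list(cgi))
    ann["sequence_class"] = annotate_sequence_class(matrix.index, list(classes))
    ann["gene_feature"] = annotate_gene_feature(matrix.index, list(genes))
    return AnnotatedMethylome(matrix=matrix, annotations=ann)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def class_category_summary(dataset: AnnotatedMethylome) -> pd.DataFrame:
    """Median normalized frequency per sample x sequence class x CpG
    category, with site counts."""
    long = dataset.matrix.copy()
    long["sequence_class"] = dataset.annotations["sequence_class"]
    long["cpg_category"] = dataset.annotations["cpg_category"]
    melted = long.melt(
        id_vars=["sequence_class", "cpg_category"],
        var_name="sample",
        value_name="frequency",
        ignore_index=True,
    )
    out = (
        melted.groupby(["sample", "sequence_class", "cpg_category"], observed=True)["frequency"]
        .agg(median="median", n_sites="size")
        .reset_index()
    )
    return out


def gene_feature_summary(dataset: AnnotatedMethylome,
                         by_class: bool = True) -> pd.DataFrame:
    """Median normalized frequency per sample x gene feature (optionally per
    sequence class)."""
    long = dataset.matrix.copy()
    long["gene_feature"] = dataset.annotations["gene_feature"]
    keys = ["gene_feature"]
    if by_class:
        long["sequence_class"] = dataset.annotations["sequence_class"]
        keys = ["sequence_class", "gene_feature"]
    melted = long.melt(id_vars=keys, var_name="sample", value_name="frequency")
    return (
        melted.groupby(["sample", *keys], observed=True)["frequency"]
        .agg(median="median", n_sites="size")
        .reset_index()
    )


@dataclass
class WindowTrack:
    """Fixed-width windows with per-sample medians and a cross-sample SD."""

    windows: pd.DataFrame          # chrom, start, end, n_sites, sd + one column per sample
    samples: list[str]
    width: int
    step: int


def window_track(dataset: AnnotatedMethylome | pd.DataFrame, genome: GenomeDef,
                 width: int = 250_000, step: Optional[int] = None) -> WindowTrack:
    """Per-window per-sample median frequency and the standard deviation of
    those medians across samples. Windows are anchored at 0 and tile each
    chromosome (``step`` defaults to ``width``, i.e. non-overlapping)."""
    if width <= 0:
        raise ValueError("width must be positive")
    step = width if step is None else step
    if not (0 < step <= width):
        raise ValueError("step must be in (0, width]")
    matrix = dataset.matrix if isinstance(dataset, AnnotatedMethylome) else dataset
    samples = list(matrix.columns)
    chroms = matrix.index.get_level_values(0).to_numpy(dtype=object)
    starts = matrix.index.get_level_values(1).to_numpy(np.int64)
    vals = matrix.to_numpy(dtype=float)
    rows = []
    for chrom in genome.names:
        sel = chroms == chrom
        pts, v = starts[sel], vals[sel]
        length = genome.length(chrom)
        for wstart in range(0, max(length, 1), step):
            wend = min(wstart + width, length)
            inside = (pts >= wstart) & (pts < wend)
            row: dict = {"chrom": chrom, "start": wstart, "end": wend,
                         "n_sites": int(inside.sum())}
            if row["n_sites"]:
                medians = np.median(v[inside], axis=0)
                for s, m in zip(samples, medians):
                    row[s] = m
                row["sd"] = float(np.std(medians, ddof=1)) if len(medians) > 1 else np.nan
            else:
                for s in samples:
                    row[s] = np.nan
                row["sd"] = np.nan
            rows.append(row)
            if wend >= length:
                break
    return WindowTrack(windows=pd.DataFrame(rows), samples=samples, width=width, step=step)


def cgi_means(dataset: AnnotatedMethylome | pd.DataFrame,
              cgi: Sequence[Interval]) -> pd.DataFrame:
    """Mean frequency over the CpGs of each (named) island, per sample, plus
    the across-sample grand mean. Islands with no covered site are omitted."""
    matrix = dataset.matrix if isinstance(dataset, AnnotatedMethylome) else dataset
    chroms = matrix.index.get_level_values(0).to_numpy(dtype=object)
    starts = matrix.index.get_level_values(1).to_numpy(np.int64)
    rows = []
    for k, island in enumerate(cgi):
        sel = (chroms == island.chrom) & (starts >= island.start) & (starts < island.end)
        if not sel.any():
            continue
        means = matrix[sel].mean(axis=0)
        row = {
            "cgi": island.name or f"CGI_{k + 1}",
            "chrom": island.chrom,
            "start": island.start,
            "end": island.end,
            "n_sites": int(sel.sum()),
            **means.to_dict(),
        }
        row["grand_mean"] = float(means.mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dispersion scan and tree comparison
# ---------------------------------------------------------------------------

@dataclass
class DispersionRegion:
    chrom: str
    start: int
    end: int
    max_sd: float
    z_score: float
    genes: list[str]
    sample_medians: dict[str, float]
    deviating_sample: str


def dispersion_scan(track: WindowTrack, genes: Sequence[GeneModel] = (),
                    top_k: int = 10, sd_z_threshold: float = 3.0) -> list[DispersionRegion]:
    """Rank windows by cross-sample SD, keep the top ``top_k`` that also
    exceed ``sd_z_threshold`` SD z-scores over the track, merge adjacent
    windows and report overlapping genes and the most deviating sample."""
    df = track.windows.dropna(subset=["sd"]).copy()
    if df.empty:
        return []
    mu, sigma = df["sd"].mean(), df["sd"].std(ddof=1)
    df["z"] = (df["sd"] - mu) / sigma if sigma and sigma > 0 else 0.0
    top = df.sort_values("sd", ascending=False).head(top_k)
    top = top[top["z"] >= sd_z_threshold]
    if top.empty:
        return []
    top = top.sort_values(["chrom", "start"])
    merged: list[list] = []
    for rec in top.itertuples():
        if merged and merged[-1][0] == rec.chrom and rec.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], rec.end)
            merged[-1][3].append(rec)
        else:
            merged.append([rec.chrom, rec.start, rec.end, [rec]])
    out = []
    for chrom, start, end, members in merged:
        best = max(members, key=lambda r: r.sd)
        medians = {s: float(np.nanmean([getattr(r, s) for r in members]))
                   for s in track.samples}
        center = float(np.median(list(medians.values())))
        deviating = max(medians, key=lambda s: abs(medians[s] - center))
        overlapping = sorted(
            g.name for g in genes
            if g.chrom == chrom and g.start < end and g.end > start
        )
        out.append(
            DispersionRegion(
                chrom=chrom, start=int(start), end=int(end),
                max_sd=float(best.sd), z_score=float(best.z),
                genes=overlapping, sample_medians=medians,
                deviating_sample=deviating,
            )
        )
    out.sort(key=lambda r: -r.max_sd)
    return out


@dataclass
class MethylomeTreeResult:
    tree: HaplogroupTree
    newick: str
    distance_matrix: pd.DataFrame
    rf_distance: Optional[int]
    reference: Optional[HaplogroupTree]


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    node = hierarchy.to_tree(link)

    def render(n) -> str:
        if n.is_leaf():
            return labels[n.id]
        left, right = render(n.left), render(n.right)
        return f"({left}:{n.dist - n.left.dist:.6g},{right}:{n.dist - n.right.dist:.6g})"

    return render(node) + ";"


def methylome_tree(matrix: pd.DataFrame, reference_tree: Optional[HaplogroupTree] = None,
                   metric: str = "correlation", linkage: str = "average") -> MethylomeTreeResult:
    """Cluster samples from their methylation profiles and compare to a
    reference phylogeny.

    Pairwise distance is 1 - Pearson correlation over shared sites by
    default (``metric="euclidean"`` switches to Euclidean distance, e.g. on
    window medians); the tree is agglomerative (UPGMA for
    ``linkage="average"``). The Robinson-Foulds distance to the reference
    topology is reported when a reference is given (0 = identical topology).
    """
    samples = list(matrix.columns)
    if len(samples) < 3:
        raise ValueError("at least 3 samples required to build a tree")
    vals = matrix.to_numpy(dtype=float)
    keep = ~np.isnan(vals).any(axis=1)
    vals = vals[keep]
    if metric == "correlation":
        dist = 1.0 - np.corrcoef(vals.T)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    elif metric == "euclidean":
        diff = vals.T[:, None, :] - vals.T[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    dm = pd.DataFrame(dist, index=samples, columns=samples)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    newick = _linkage_to_newick(link, samples)
    rf = None
    ref = reference_tree
    if ref is not None:
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=ref.as_newick(), schema="newick", taxon_namespace=taxa)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
    tree = HaplogroupTree.from_newick(newick)
    return MethylomeTreeResult(
        tree=tree, newick=newick, distance_matrix=dm, rf_distance=rf, reference=ref
    )


# ---------------------------------------------------------------------------
# bedGraph output
# ---------------------------------------------------------------------------

def write_window_bedgraph(track: WindowTrack, sample: str, path) -> None:
    """One bedGraph line per non-empty window for one sample (or "sd")."""
    col = sample
    with open(path, "w") as fh:
        for rec in track.windows.itertuples():
            val = getattr(rec, col)
            if val == val:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{val:.6g}\n")
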