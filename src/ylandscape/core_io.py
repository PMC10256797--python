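"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate convention: everything in memory is 0-based, half-open. VCF
(1-based) is converted at the boundary — internal start = VCF POS - 1 — and
converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .intervals import Interval
from .sv import (
    HET_ALT,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SV_TYPES,
    SVPanel,
    SVRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Genome definition
# ---------------------------------------------------------------------------

@dataclass
class GenomeDef:
    """Chromosome lengths, assembly gaps (N stretches) and per-chromosome
    ploidy: the denominator universe for coverage and enrichment.

    The effective ("without N") size of a chromosome is its length minus the
    total gap length; the ploidy-weighted sum over all chromosomes is the
    diploid genome size without N.
    """

    chromosomes: list[tuple[str, int]]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    ploidy: dict[str, int] = field(default_factory=dict)
    default_ploidy: int = 2

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {name}: length must be a positive integer")
        for name in self.gaps:
            if name not in self._lengths:
                raise ValueError(f"gap interval references unknown chromosome {name!r}")
        for name in self.ploidy:
            if name not in self._lengths:
                raise ValueError(f"ploidy entry references unknown chromosome {name!r}")
            if self.ploidy[name] < 1:
                raise ValueError(f"ploidy of {name} must be a positive integer")
        # normalize: merge, then clip to chromosome bounds
        self.gaps = {
            name: iv.clip(iv.normalize(gs), 0, self._lengths[name])
            for name, gs in self.gaps.items()
            if gs
        }

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def gap_length(self, chrom: str) -> int:
        return sum(e - s for s, e in self.gaps.get(chrom, []))

    def non_n_size(self, chrom: str) -> int:
        return self.length(chrom) - self.gap_length(chrom)

    def chrom_ploidy(self, chrom: str) -> int:
        return self.ploidy.get(chrom, self.default_ploidy)

    @property
    def diploid_non_n_size(self) -> int:
        """Genome size without N, each chromosome counted ploidy times."""
        return sum(self.non_n_size(c) * self.chrom_ploidy(c) for c in self.names)

    def weight(self, chrom: str) -> float:
        """Share of the ploidy-weighted non-N genome held by ``chrom``."""
        return self.non_n_size(chrom) * self.chrom_ploidy(chrom) / self.diploid_non_n_size


def read_genome_def(
    sizes_path: PathLike,
    gaps_path: Optional[PathLike] = None,
    ploidy_config: Union[None, PathLike, dict[str, int]] = None,
    default_ploidy: int = 2,
) -> GenomeDef:
    """Build a GenomeDef from a 2-column sizes TSV, an optional gap BED3 and
    an optional ploidy override table (dict or YAML file)."""
    chroms: list[tuple[str, int]] = []
    with open(sizes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{sizes_path}:{lineno}: expected 2 columns")
            name, raw = parts[0], parts[1]
            try:
                length = int(raw)
            except ValueError:
                raise ValueError(f"{sizes_path}:{lineno}: non-integer length {raw!r}") from None
            if length <= 0:
                raise ValueError(f"{sizes_path}:{lineno}: non-positive length for {name}")
            chroms.append((name, length))
    gaps: dict[str, list[tuple[int, int]]] = {}
    if gaps_path is not None:
        for interval in read_bed(gaps_path):
            gaps.setdefault(interval.chrom, []).append((interval.start, interval.end))
    ploidy: dict[str, int] = {}
    if isinstance(ploidy_config, dict):
        ploidy = {k: int(v) for k, v in ploidy_config.items()}
    elif ploidy_config is not None:
        with open(ploidy_config) as fh:
            loaded = yaml.safe_load(fh) or {}
        ploidy = {k: int(v) for k, v in loaded.items()}
    return GenomeDef(chroms, gaps, ploidy, default_ploidy=default_ploidy)


# ---------------------------------------------------------------------------
# Mapping summaries
# ---------------------------------------------------------------------------

@dataclass
class MappingSummary:
    """Per-chromosome mapped base counts for one sample."""

    sample: str
    mapped_bases: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, n in self.mapped_bases.items():
            if n < 0:
                raise ValueError(f"negative mapped bases for {chrom}")

    @property
    def total_mapped_bases(self) -> int:
        return sum(self.mapped_bases.values())

    def get(self, chrom: str) -> int:
        return self.mapped_bases.get(chrom, 0)


def read_mapping_summary(path: PathLike) -> list[MappingSummary]:
    """Read a TSV with columns sample, chrom, mapped_bases (one summary per
    sample; duplicate (sample, chrom) rows are summed with a warning)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = {"sample", "chrom", "mapped_bases"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"{path}: no records")
    if (df["mapped_bases"] < 0).any():
        raise ValueError(f"{path}: negative mapped_bases")
    if df.duplicated(["sample", "chrom"]).any():
        logger.warning("%s: duplicate (sample, chrom) rows summed", path)
    grouped = df.groupby(["sample", "chrom"], sort=False)["mapped_bases"].sum()
    out = []
    for sample in df["sample"].unique():
        counts = {c: int(v) for (s, c), v in grouped.items() if s == sample}
        out.append(MappingSummary(sample=sample, mapped_bases=counts))
    return out


def write_mapping_summary(summaries: Iterable[MappingSummary], path: PathLike) -> None:
    rows = [
        {"sample": s.sample, "chrom": c, "mapped_bases": n}
        for s in summaries
        for c, n in s.mapped_bases.items()
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "mapped_bases"]).to_csv(
        path, sep="\t", index=False
    )


def ingest_alignments(alignment_path: PathLike, genome: Optional[GenomeDef] = None,
                      sample: Optional[str] = None) -> MappingSummary:
    """Summarize an alignment file (SAM/BAM/CRAM) into mapped bases per
    chromosome, counting aligned query bases of primary alignments only
    (secondary and supplementary records are excluded)."""
    import pysam

    counts: dict[str, int] = {}
    n_primary = 0
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_primary += 1
            counts[rec.reference_name] = counts.get(rec.reference_name, 0) + (
                rec.query_alignment_length or 0
            )
    if n_primary == 0:
        logger.warning("%s: no mapped primary alignments; all-zero summary", alignment_path)
    if genome is not None:
        unknown = set(counts) - set(genome.names)
        if unknown:
            logger.warning(
                "%s: alignments to chromosomes absent from genome definition: %s",
                alignment_path,
                ", ".join(sorted(unknown)),
            )
    name = sample if sample is not None else Path(alignment_path).stem
    return MappingSummary(sample=name, mapped_bases=counts)


# ---------------------------------------------------------------------------
# SV VCF dialect
# ---------------------------------------------------------------------------

_GT_TO_CODE = {HOM_REF: "0/0", HET_ALT: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
    '##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">',
]


def _parse_gt(token: str) -> str:
    allele = token.split(":")[0].replace("|", "/")
    if allele in (".", "./.", ".|."):
        return MISSING
    alleles = [a for a in allele.split("/") if a != ""]
    if any(a == "." for a in alleles):
        return MISSING
    alts = sum(a != "0" for a in alleles)
    if alts == 0:
        return HOM_REF
    if len(alleles) == 1 or alts == len(alleles):
        return HOM_ALT
    return HET_ALT


def read_sv_vcf(path: PathLike, platform: str = "") -> SVPanel:
    """Read the SV VCF dialect (SVTYPE/SVLEN/END in INFO, GT[:GQ] per
    sample). Records lacking SVTYPE are rejected with a logged reason;
    IMPRECISE records are retained and tagged for later filtering."""
    records: list[SVRecord] = []
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                logger.warning("%s:%d: short record skipped", path, lineno)
                continue
            chrom, pos, rid, _ref, _alt, qual, _filt, info = fields[:8]
            info_map: dict[str, str] = {}
            flags: set[str] = set()
            for item in info.split(";"):
                if not item or item == ".":
                    continue
                if "=" in item:
                    k, v = item.split("=", 1)
                    info_map[k] = v
                else:
                    flags.add(item)
            svtype = info_map.get("SVTYPE")
            if svtype is None or svtype not in SV_TYPES and svtype != "BND":
                logger.warning("%s:%d: record rejected (missing or unknown SVTYPE)", path, lineno)
                continue
            if svtype == "BND":
                svtype = "TRA"
            if "SVLEN" in info_map:
                length = abs(int(float(info_map["SVLEN"])))
            elif "END" in info_map:
                length = int(info_map["END"]) - int(pos)
            else:
                logger.warning("%s:%d: record rejected (no SVLEN or END)", path, lineno)
                continue
            length = max(length, 1)
            rec_qual = float(qual) if qual not in (".", "") else float("nan")
            fmt = fields[8].split(":") if len(fields) > 8 else []
            gq_idx = fmt.index("GQ") if "GQ" in fmt else None
            genotypes: dict[str, str] = {}
            qualities: dict[str, float] = {}
            for sample, token in zip(samples, fields[9:]):
                genotypes[sample] = _parse_gt(token)
                if gq_idx is not None:
                    parts = token.split(":")
                    try:
                        qualities[sample] = float(parts[gq_idx])
                    except (IndexError, ValueError):
                        qualities[sample] = rec_qual
                else:
                    qualities[sample] = rec_qual
            records.append(
                SVRecord(
                    chrom=chrom,
                    start=int(pos) - 1,
                    svtype=svtype,
                    length=length,
                    genotypes=genotypes,
                    qualities=qualities,
                    precise="IMPRECISE" not in flags,
                    record_id=None if rid == "." else rid,
                )
            )
    return SVPanel(records, samples, platform=platform)


def write_sv_vcf(panel: SVPanel, path: PathLike) -> None:
    """Write a panel back to the SV VCF dialect (inverse of read_sv_vcf)."""
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + list(panel.samples)) + "\n")
        for i, rec in enumerate(panel.records):
            svlen = -rec.length if rec.svtype == "DEL" else rec.length
            info = [
                "PRECISE" if rec.precise else "IMPRECISE",
                f"SVTYPE={rec.svtype}",
                f"SVLEN={svlen}",
                f"END={rec.start + rec.length if rec.svtype != 'INS' else rec.start + 1}",
            ]
            cols = [
                rec.chrom,
                str(rec.start + 1),
                rec.record_id or f"sv{i + 1}",
                "N",
                f"<{rec.svtype}>",
                ".",
                "PASS",
                ";".join(info),
                "GT:GQ",
            ]
            for s in panel.samples:
                q = rec.qualities.get(s, float("nan"))
                qtxt = "." if q != q else f"{q:g}"
                cols.append(f"{_GT_TO_CODE[rec.genotypes.get(s, MISSING)]}:{qtxt}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED, gene models, trees
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[Interval]:
    """Read BED3/BED6 into Interval records (name from column 4, strand 6)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            out.append(
                Interval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 and parts[3] != "." else None,
                    strand=parts[5] if len(parts) > 5 and parts[5] in "+-" else None,
                )
            )
    return out


def write_bed(records: Iterable[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            name = r.name if r.name is not None else "."
            if r.strand is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")
            elif r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


#: width of the TSS region (bases immediately upstream of the strand-aware
#: transcription start)
TSS_REGION_WIDTH = 200
#: extent of the "upstream" feature beyond the TSS region
UPSTREAM_WIDTH = 2000

#: gene-feature priority, highest first, matching the annotation priority
#: used for overlapping regions (promoter/TSS, UTRs, first exon, other
#: exons, introns, upstream)
FEATURE_PRIORITY = ("tss", "utr5", "utr3", "first_exon", "exon", "intron", "upstream")


@dataclass
class GeneModel:
    """A transcript model with strand-aware derived features.

    The TSS region is exactly 200 bp adjacent to the strand-aware
    transcription start; UTRs come from the thick (CDS) bounds; introns are
    the gaps between exons.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    exons: list[tuple[int, int]]
    thick_start: Optional[int] = None
    thick_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")
        self.exons = iv.normalize(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.name}: exon outside transcript bounds")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start position."""
        return self.start if self.strand == "+" else self.end

    def raw_features(self) -> dict[str, list[tuple[int, int]]]:
        """Feature intervals before priority resolution (may overlap)."""
        feats: dict[str, list[tuple[int, int]]] = {k: [] for k in FEATURE_PRIORITY}
        if self.strand == "+":
            feats["tss"] = iv.clip([(self.start - TSS_REGION_WIDTH, self.start)], 0, self.start)
            feats["upstream"] = iv.clip(
                [(self.start - TSS_REGION_WIDTH - UPSTREAM_WIDTH, self.start - TSS_REGION_WIDTH)],
                0,
                self.start,
            )
        else:
            feats["tss"] = [(self.end, self.end + TSS_REGION_WIDTH)]
            feats["upstream"] = [
                (self.end + TSS_REGION_WIDTH, self.end + TSS_REGION_WIDTH + UPSTREAM_WIDTH)
            ]
        coding = (
            self.thick_start is not None
            and self.thick_end is not None
            and self.thick_start < self.thick_end
        )
        if coding:
            if self.strand == "+":
                left, right = "utr5", "utr3"
            else:
                left, right = "utr3", "utr5"
            for s, e in self.exons:
                for us, ue in iv.clip([(s, e)], self.start, self.thick_start):
                    feats[left].append((us, ue))
                for us, ue in iv.clip([(s, e)], self.thick_end, self.end):
                    feats[right].append((us, ue))
        first = self.exons[0] if self.strand == "+" else self.exons[-1]
        feats["first_exon"] = [first]
        feats["exon"] = [e for e in self.exons if e != first]
        prev_end = None
        for s, e in self.exons:
            if prev_end is not None and s > prev_end:
                feats["intron"].append((prev_end, s))
            prev_end = e
        return feats

    def features(self) -> dict[str, list[tuple[int, int]]]:
        """Priority-resolved features: each base gets exactly one label."""
        raw = self.raw_features()
        taken: list[tuple[int, int]] = []
        resolved: dict[str, list[tuple[int, int]]] = {}
        for feat in FEATURE_PRIORITY:
            ivs = iv.normalize(raw[feat]) if raw[feat] else []
            resolved[feat] = iv.subtract(ivs, taken) if ivs else []
            taken = iv.normalize(taken + resolved[feat])
        return resolved


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read a BED12-like gene table (blocks = exons, thick = CDS)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5]
            thick_start, thick_end = int(p[6]), int(p[7])
            n_blocks = int(p[9])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            starts = [int(x) for x in p[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            genes.append(
                GeneModel(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=name,
                    strand=strand,
                    exons=exons,
                    thick_start=thick_start,
                    thick_end=thick_end,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            ts = g.thick_start if g.thick_start is not None else g.start
            te = g.thick_end if g.thick_end is not None else g.start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.start, g.end, g.name, 0, g.strand,
                        ts, te, "0,0,0", len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )


@dataclass
class HaplogroupTree:
    """A rooted sample phylogeny (leaf labels = sample names)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_names
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, newick: str) -> "HaplogroupTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick(path: PathLike) -> HaplogroupTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return HaplogroupTree(tree)
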