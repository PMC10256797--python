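"""Post-caller structural-variant processing.

Consumes per-sample SV call sets (already produced by a long-read caller),
and implements the panel-construction steps used for a hemizygous
chromosome: dropping breakpoint-imprecise calls, merging insertions and
deletions separately within a positional distance, masking low-quality
genotypes, removing events that are reference in every sample, size-bin
classification, repeat-content annotation and phylogeny sharing profiles.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, intersect_length, normalize

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET_ALT = "het_alt"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = (HOM_REF, HET_ALT, HOM_ALT, MISSING)
INDEL_TYPES = ("INS", "DEL")
SV_TYPES = ("INS", "DEL", "DUP", "TRA")

#: smallest indel length admitted to the panel (caller comparison floor)
MIN_INDEL_LENGTH = 10

SIZE_BINS = {
    "small": (10, 50),      # [10, 50)
    "sv": (50, 500),        # [50, 500)
    "large": (500, None),   # [500, inf)
}


@dataclass
class SVRecord:
    """One structural variant with per-sample genotypes.

    ``start`` is 0-based; ``length`` is the absolute event size in bp.
    ``qualities`` holds the per-sample genotype quality (record-level QUAL
    is propagated to every sample when no per-genotype field exists).
    """

    chrom: str
    start: int
    svtype: str
    length: int
    genotypes: dict[str, str]
    qualities: dict[str, float]
    precise: bool = True
    record_id: Optional[str] = None
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype in INDEL_TYPES and self.length < 1:
            raise ValueError("indel length must be >= 1")
        for gt in self.genotypes.values():
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r}")

    @property
    def end(self) -> int:
        return self.start + max(self.length, 1)

    def is_indel(self) -> bool:
        return self.svtype in INDEL_TYPES


@dataclass
class SVPanel:
    """An ordered set of SVRecords sharing one sample set."""

    records: list[SVRecord]
    samples: list[str]
    platform: str = ""

    def __post_init__(self) -> None:
        for rec in self.records:
            extra = set(rec.genotypes) - set(self.samples)
            if extra:
                raise ValueError(f"record genotyped for unknown samples {sorted(extra)}")
            # absent samples are explicit missing calls
            for s in self.samples:
                rec.genotypes.setdefault(s, MISSING)
                rec.qualities.setdefault(s, float("nan"))

    def __len__(self) -> int:
        return len(self.records)


def filter_imprecise(panel: SVPanel) -> SVPanel:
    """Drop records whose breakpoints the caller flagged as imprecise."""
    kept = [r for r in panel.records if r.precise]
    removed = len(panel.records) - len(kept)
    if removed:
        logger.info("filter_imprecise: removed %d imprecise record(s)", removed)
    return SVPanel(kept, list(panel.samples), panel.platform)


def _cluster_positions(starts: Sequence[int], max_distance: int) -> list[list[int]]:
    """Single-linkage clustering of sorted positions: a chain breaks where
    consecutive starts are more than ``max_distance`` apart."""
    order = np.argsort(starts, kind="stable")
    clusters: list[list[int]] = []
    prev = None
    for idx in order:
        pos = starts[idx]
        if prev is not None and pos - prev <= max_distance:
            clusters[-1].append(int(idx))
        else:
            clusters.append([int(idx)])
        prev = pos
    return clusters


def merge_indels(panels: Sequence[SVPanel] | SVPanel, max_distance: int = 100) -> SVPanel:
    """Merge insertion and deletion calls across panels into unique events.

    Insertions and deletions are merged separately, per chromosome, by
    single-linkage clustering of start positions at ``max_distance`` (100 bp
    by default, so calls 100 bp up- or downstream join one event). The
    merged record takes the position/length of its first member in position
    order; each sample's genotype comes from that sample's own member call,
    or missing if the sample contributed none. Non-indel records (DUP/TRA)
    pass through unmerged.
    """
    if isinstance(panels, SVPanel):
        panels = [panels]
    samples: list[str] = []
    for p in panels:
        for s in p.samples:
            if s not in samples:
                samples.append(s)

    indels: list[SVRecord] = []
    others: list[SVRecord] = []
    for p in panels:
        for r in p.records:
            (indels if r.is_indel() else others).append(r)

    groups: dict[tuple[str, str], list[SVRecord]] = defaultdict(list)
    for r in indels:
        groups[(r.chrom, r.svtype)].append(r)

    merged: list[SVRecord] = []
    for (chrom, svtype), recs in groups.items():
        recs = sorted(recs, key=lambda r: (r.start, r.length))
        for cluster in _cluster_positions([r.start for r in recs], max_distance):
            members = [recs[i] for i in sorted(cluster)]
            rep = members[0]
            genotypes: dict[str, str] = {}
            quals: dict[str, float] = {}
            for m in members:
                for s, gt in m.genotypes.items():
                    if gt == MISSING:
                        continue
                    q = m.qualities.get(s, float("nan"))
                    if s in genotypes and genotypes[s] != gt:
                        # two member calls of one sample disagree: keep the
                        # higher-quality genotype
                        logger.info(
                            "merge conflict at %s:%d (%s) for sample %s", chrom, rep.start, svtype, s
                        )
                        if not (q > quals[s]):
                            continue
                    if s not in genotypes or (q == q and not (quals.get(s, float("-inf")) >= q)):
                        genotypes[s] = gt
                        quals[s] = q
            provenance = sorted(
                {f"{m.chrom}:{m.start}:{m.svtype}" for m in members}
                | {x for m in members for x in m.members}
            )
            merged.append(
                SVRecord(
                    chrom=chrom,
                    start=rep.start,
                    svtype=svtype,
                    length=rep.length,
                    genotypes=genotypes,
                    qualities=quals,
                    precise=rep.precise,
                    record_id=rep.record_id,
                    members=provenance,
                )
            )
    merged.extend(others)
    merged.sort(key=lambda r: (r.chrom, r.start, r.svtype))
    return SVPanel(merged, samples, platform=";".join(sorted({p.platform for p in panels if p.platform})))


def filter_genotypes(panel: SVPanel, min_quality: float = 25.0) -> SVPanel:
    """Mask genotypes with quality under ``min_quality`` and drop events
    that are homozygous reference (or missing) in every sample."""
    kept: list[SVRecord] = []
    for rec in panel.records:
        genotypes = dict(rec.genotypes)
        for s, gt in genotypes.items():
            q = rec.qualities.get(s, float("nan"))
            if gt != MISSING and q == q and q < min_quality:
                genotypes[s] = MISSING
        if any(gt in (HET_ALT, HOM_ALT) for gt in genotypes.values()):
            kept.append(replace(rec, genotypes=genotypes))
    dropped = len(panel.records) - len(kept)
    if dropped:
        logger.info("filter_genotypes: dropped %d event(s) with no alternative call", dropped)
    return SVPanel(kept, list(panel.samples), panel.platform)


def classify_size(record: SVRecord | int) -> str:
    """Size bin of an indel: small [10,50), sv [50,500), large [500,inf)."""
    length = record.length if isinstance(record, SVRecord) else int(record)
    if isinstance(record, SVRecord) and not record.is_indel():
        raise ValueError("size bins apply to insertions and deletions only")
    if length < MIN_INDEL_LENGTH:
        raise ValueError(f"indel length {length} below the {MIN_INDEL_LENGTH} bp panel floor")
    if length < 50:
        return "small"
    if length < 500:
        return "sv"
    return "large"


def repeat_fraction(record: SVRecord, repeats: Iterable[Interval]) -> tuple[float, Optional[str]]:
    """Fraction of the variant footprint covered by repeat annotation, and
    the repeat class covering the most bases (ties broken lexicographically).
    """
    footprint = [(record.start, record.end)]
    if record.end <= record.start:
        raise ValueError("zero-length variant footprint")
    by_class: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in repeats:
        if iv.chrom == record.chrom:
            by_class[iv.name or "repeat"].append((iv.start, iv.end))
    if not by_class:
        return 0.0, None
    all_repeats = [iv for ivs in by_class.values() for iv in ivs]
    covered = intersect_length(footprint, all_repeats)
    fraction = covered / (record.end - record.start)
    if covered == 0:
        return 0.0, None
    per_class = {
        cls: intersect_length(footprint, normalize(ivs)) for cls, ivs in by_class.items()
    }
    dominant = min(per_class, key=lambda c: (-per_class[c], c))
    return fraction, dominant


@dataclass
class SharingProfile:
    """Counts of carrier patterns among variants genotyped in all samples."""

    n_complete: int
    pattern_counts: "Counter[frozenset[str]]"
    singletons: dict[str, int]
    shared_by_all: int
    samples: list[str]

    @property
    def fraction_shared(self) -> float:
        return self.shared_by_all / self.n_complete if self.n_complete else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Pattern membership matrix (one row per pattern) for upset-style plots."""
        rows = []
        for pattern, count in sorted(
            self.pattern_counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        ):
            row = {s: (s in pattern) for s in self.samples}
            row["n_variants"] = count
            row["n_carriers"] = len(pattern)
            rows.append(row)
        return pd.DataFrame(rows)


def sharing_profile(matrix: pd.DataFrame, tree=None) -> SharingProfile:
    """Carrier-pattern counts over variants with genotype calls in all samples.

    ``matrix`` is variants x samples with values 1 (present), 0 (absent) and
    NaN (missing); only complete rows (no missing call) enter the counts, as
    in the study's sharing figure. If a phylogeny is given its leaf set must
    equal the sample set.
    """
    samples = list(matrix.columns)
    if tree is not None:
        leaves = set(tree.leaf_names) if hasattr(tree, "leaf_names") else {
            lf.taxon.label for lf in tree.leaf_node_iter()
        }
        if leaves != set(samples):
            raise ValueError(
                f"tree leaves {sorted(leaves)} do not match panel samples {sorted(samples)}"
            )
    complete = matrix.dropna(axis=0, how="any")
    counts: Counter[frozenset[str]] = Counter()
    for _, row in complete.iterrows():
        carriers = frozenset(s for s in samples if row[s] == 1)
        if carriers:
            counts[carriers] += 1
    singletons = {s: counts.get(frozenset({s}), 0) for s in samples}
    shared = counts.get(frozenset(samples), 0)
    return SharingProfile(
        n_complete=len(complete),
        pattern_counts=counts,
        singletons=singletons,
        shared_by_all=shared,
        samples=samples,
    )
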