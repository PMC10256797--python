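"""Per-chromosome coverage and enrichment factor for selective sequencing.

Coverage of a chromosome is mapped bases divided by its size without N
gaps. The enrichment factor compares a chromosome's share of all mapped
bases with its expected share given its ploidy-weighted non-N size:

    EF(c) = (mapped(c) / total_mapped) / (nonN(c) * ploidy(c) / diploid_nonN)

EF = 1 means no enrichment; the summary reports the target chromosome's EF
alongside the mean and standard deviation over autosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeDef, MappingSummary

#: default pattern for chromosomes excluded from the autosome mean/SD
_NON_AUTOSOME = re.compile(r"^(chr)?(X|Y|M|MT)$", re.IGNORECASE)


@dataclass
class EnrichmentResult:
    """Coverage and enrichment factors for one sample."""

    sample: str
    coverage: dict[str, float]
    enrichment: dict[str, float]
    target: Optional[str] = None
    autosomes: list[str] = field(default_factory=list)

    @property
    def target_enrichment(self) -> float:
        if self.target is None:
            return float("nan")
        return self.enrichment[self.target]

    @property
    def autosome_mean(self) -> float:
        vals = [self.enrichment[c] for c in self.autosomes]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def autosome_sd(self) -> float:
        vals = [self.enrichment[c] for c in self.autosomes]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def _autosome_names(genome: GenomeDef, exclude: Iterable[str] = ()) -> list[str]:
    excluded = set(exclude)
    return [
        c
        for c in genome.names
        if c not in excluded and not _NON_AUTOSOME.match(c) and "_" not in c
    ]


def chromosome_coverage(summary: MappingSummary, genome: GenomeDef) -> dict[str, float]:
    """Mapped bases over non-N size, per chromosome of the genome."""
    unknown = set(summary.mapped_bases) - set(genome.names)
    if unknown:
        raise ValueError(
            "mapped bases on chromosome(s) absent from genome definition: "
            + ", ".join(sorted(unknown))
        )
    cov: dict[str, float] = {}
    for chrom in genome.names:
        mapped = summary.get(chrom)
        non_n = genome.non_n_size(chrom)
        if non_n == 0:
            if mapped > 0:
                raise ValueError(f"chromosome {chrom}: mapped bases but zero non-N size")
            cov[chrom] = 0.0
        else:
            cov[chrom] = mapped / non_n
    return cov


def enrichment_factor(
    summary: MappingSummary,
    genome: GenomeDef,
    target: Optional[str] = None,
    merge_into_target: Sequence[str] = (),
) -> EnrichmentResult:
    """Enrichment factors for every chromosome of the genome.

    Chromosomes with zero mapped bases are reported with EF 0 rather than
    dropped. ``merge_into_target`` lists unplaced contigs pooled with the
    target (mapped bases and ploidy-weighted sizes summed) before the ratio
    is taken, as when a target chromosome and its unplaced contig are
    enriched jointly.
    """
    coverage = chromosome_coverage(summary, genome)
    total = summary.total_mapped_bases
    if total <= 0:
        raise ValueError("total mapped bases must be positive")
    diploid = genome.diploid_non_n_size
    if diploid <= 0:
        raise ValueError("diploid non-N genome size must be positive")

    merged = set(merge_into_target)
    if merged and target is None:
        raise ValueError("merge_into_target requires a target chromosome")

    ef: dict[str, float] = {}
    for chrom in genome.names:
        if chrom in merged:
            continue
        mapped = summary.get(chrom)
        weight = genome.non_n_size(chrom) * genome.chrom_ploidy(chrom)
        if chrom == target and merged:
            mapped += sum(summary.get(c) for c in merged)
            weight += sum(genome.non_n_size(c) * genome.chrom_ploidy(c) for c in merged)
        if weight == 0:
            ef[chrom] = 0.0
        else:
            ef[chrom] = (mapped / total) / (weight / diploid)
    autosomes = _autosome_names(genome, exclude={target} | merged if target else merged)
    return EnrichmentResult(
        sample=summary.sample,
        coverage=coverage,
        enrichment=ef,
        target=target,
        autosomes=autosomes,
    )


def expected_enrichment(fold: float, target_share: float) -> float:
    """Closed-form expected EF of a target enriched ``fold``-fold when it
    holds ``target_share`` of the ploidy-weighted non-N genome."""
    w = target_share
    return fold / (w * fold + 1.0 - w)


def enrichment_report(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Per-sample summary table: target EF and autosome mean +/- SD."""
    if not results:
        raise ValueError("at least one result required")
    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample,
                "target": r.target,
                "target_enrichment": r.target_enrichment,
                "autosome_mean": r.autosome_mean,
                "autosome_sd": r.autosome_sd,
            }
        )
    return pd.DataFrame(rows)


def enrichment_table(result: EnrichmentResult) -> pd.DataFrame:
    """Long-form per-chromosome table for one sample."""
    return pd.DataFrame(
        {
            "chrom": list(result.enrichment),
            "coverage": [result.coverage[c] for c in result.enrichment],
            "enrichment_factor": [result.enrichment[c] for c in result.enrichment],
        }
    )


def plot_enrichment(result: EnrichmentResult, ax=None):
    """Horizontal bar chart of enrichment factors with the EF = 1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    chroms = list(result.enrichment)
    ax.barh(range(len(chroms)), [result.enrichment[c] for c in chroms])
    ax.set_yticks(range(len(chroms)), chroms)
    ax.axvline(1.0, linestyle="--", color="grey")
    ax.set_xlabel("enrichment factor")
    ax.set_title(result.sample)
    ax.invert_yaxis()
    return ax
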