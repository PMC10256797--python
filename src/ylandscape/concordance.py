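"""Cross-platform genotype concordance for hemizygous variant panels.

Genotype calls are binarized into presence/absence (on a hemizygous
chromosome any alternative call — het or hom — implies carrier status), and
pairwise agreement between samples or platforms is measured with the phi
coefficient (Matthews correlation coefficient), the Pearson correlation of
two binary variables:

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)

Significance comes from the 2x2 contingency table (Fisher's exact test by
default, chi-square n*phi^2 as an option), Bonferroni-corrected over the
pairs actually tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sv import HET_ALT, HOM_ALT, HOM_REF, MISSING, SVPanel


@dataclass
class BinaryGenotypeMatrix:
    """Variants x samples presence/absence matrix (NaN = missing call)."""

    data: pd.DataFrame
    platforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("binary matrix values must be 0, 1 or missing")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


_BINARY = {HOM_ALT: 1.0, HET_ALT: 1.0, HOM_REF: 0.0, MISSING: float("nan")}


def binarize(panel: SVPanel) -> BinaryGenotypeMatrix:
    """Presence (1) / absence (0) matrix: het and hom alternative calls are
    present, hom reference absent, missing stays missing."""
    rows = []
    index = []
    for i, rec in enumerate(panel.records):
        rows.append([_BINARY[rec.genotypes.get(s, MISSING)] for s in panel.samples])
        index.append(rec.record_id or f"{rec.chrom}:{rec.start}:{rec.svtype}:{i}")
    df = pd.DataFrame(rows, index=index, columns=panel.samples, dtype=float)
    platforms = {s: panel.platform for s in panel.samples}
    return BinaryGenotypeMatrix(df, platforms)


@dataclass
class PhiResult:
    """Phi coefficient of two binary vectors over pairwise-complete entries."""

    phi: float
    n: int
    table: np.ndarray  # 2x2 counts [[n00, n01], [n10, n11]]
    undefined_reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def phi(x, y) -> PhiResult:
    """Phi coefficient from the 2x2 table of two binary vectors.

    Entries missing in either vector are dropped; if any table margin is
    zero the coefficient is undefined and reported as such (never as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(keep.sum())
    table = np.zeros((2, 2), dtype=np.int64)
    for xi in (0, 1):
        for yi in (0, 1):
            table[xi, yi] = int(np.sum((x == xi) & (y == yi)))
    if n == 0:
        return PhiResult(float("nan"), 0, table, "no informative positions")
    r0, r1 = table.sum(axis=1)
    c0, c1 = table.sum(axis=0)
    if min(r0, r1, c0, c1) == 0:
        return PhiResult(float("nan"), n, table, "degenerate margin (all-0 or all-1 vector)")
    num = float(table[1, 1] * table[0, 0] - table[1, 0] * table[0, 1])
    denom = math.sqrt(float(r0) * float(r1) * float(c0) * float(c1))
    return PhiResult(num / denom, n, table)


@dataclass
class ConcordanceResult:
    """Pairwise phi matrix with significance after Bonferroni correction."""

    phi: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    n_informative: pd.DataFrame
    alpha: float
    n_tests: int
    method: str


def _pair_p_value(res: PhiResult, method: str) -> float:
    if method == "fisher":
        return float(stats.fisher_exact(res.table)[1])
    if method == "chi2":
        # chi-square statistic of a 2x2 table equals n * phi^2, df = 1
        return float(stats.chi2.sf(res.n * res.phi**2, df=1))
    raise ValueError(f"unknown significance method {method!r}")


def phi_matrix(
    matrix: BinaryGenotypeMatrix | pd.DataFrame,
    alpha: float = 0.05,
    method: str = "fisher",
) -> ConcordanceResult:
    """All-pairs phi over the columns of a binary matrix, with p-values
    Bonferroni-corrected over the pairs actually tested (those with a
    defined coefficient)."""
    df = matrix.data if isinstance(matrix, BinaryGenotypeMatrix) else matrix
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("at least two columns required")
    phi_m = pd.DataFrame(np.nan, index=cols, columns=cols)
    p_m = pd.DataFrame(np.nan, index=cols, columns=cols)
    n_m = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    tested = []
    for a, b in itertools.combinations(cols, 2):
        res = phi(df[a].to_numpy(), df[b].to_numpy())
        n_m.loc[a, b] = n_m.loc[b, a] = res.n
        if res.defined:
            phi_m.loc[a, b] = phi_m.loc[b, a] = res.phi
            p = _pair_p_value(res, method)
            p_m.loc[a, b] = p_m.loc[b, a] = p
            tested.append((a, b))
    for c in cols:
        res = phi(df[c].to_numpy(), df[c].to_numpy())
        if res.defined:
            phi_m.loc[c, c] = res.phi
    m = len(tested)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    if m:
        threshold = alpha / m
        for a, b in tested:
            s = bool(p_m.loc[a, b] <= threshold)
            sig.loc[a, b] = sig.loc[b, a] = s
    return ConcordanceResult(
        phi=phi_m,
        p_values=p_m,
        significant=sig,
        n_informative=n_m,
        alpha=alpha,
        n_tests=m,
        method=method,
    )


def population_presence(
    genotypes: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Collapse a variants x individuals 0/1/NaN table to per-group presence.

    A variant is present in a group iff its carrier frequency among
    genotyped individuals is strictly greater than ``threshold`` (0.2 by
    default); a group with no genotyped individual gets a missing call.
    """
    out = {}
    for group in sorted(set(groups.values())):
        members = [c for c in genotypes.columns if groups.get(c) == group]
        sub = genotypes[members]
        genotyped = sub.notna().sum(axis=1)
        freq = sub.sum(axis=1, skipna=True) / genotyped
        presence = (freq > threshold).astype(float)
        presence[genotyped == 0] = np.nan
        out[group] = presence
    return pd.DataFrame(out, index=genotypes.index)


def plot_phi_heatmap(result: ConcordanceResult, ax=None):
    """Heatmap of phi values, masking pairs not significant after Bonferroni."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    shown = result.phi.where(result.significant | np.eye(len(result.phi), dtype=bool))
    im = ax.imshow(shown.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(shown.columns)), shown.columns, rotation=90)
    ax.set_yticks(range(len(shown.index)), shown.index)
    plt.colorbar(im, ax=ax, label="phi")
    return ax
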