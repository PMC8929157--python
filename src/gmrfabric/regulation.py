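"""Significant-regulation calls and weighted regulation scores.

A gene is called significantly regulated between the normal tissue and a
cancer nodule only when two conditions hold at once:

1. its absolute expression ratio exceeds a *gene-specific* cutoff
   ``CUT = 1 + (1/100) * sqrt(2 * (REV_normal^2 + REV_cancer^2))`` that grows
   with the gene's own biological variability plus technical noise, replacing
   arbitrary uniform fold-change thresholds (1.5x, 2x); and
2. a heteroscedastic (Welch) t-test on the log2 replicate values rejects
   equality of means at p < 0.05, Bonferroni-corrected over the gene's
   redundant spots (gene p = min(1, Ri * min_k p_k)).

The conjunction makes the criterion conservative under the null.

The Weighted Individual gene Regulation (WIR) then grades every gene —
significant or not — by how much its change matters::

    WIR = AVE_normal * sign(x) * (|x| - 1) * (1 - p)

so an abundant, confidently-shifted gene outweighs a rare or noisy one with
the same fold-change. Averaging WIR over a pathway's quantified members gives
the Weighted Pathway Regulation (WPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionDataset, require_valid
from .fabric import compute_ave, compute_rev

__all__ = [
    "RegulationRecord",
    "PathwayRegulation",
    "regulation_cutoff",
    "signed_ratio",
    "gene_pvalue",
    "test_regulation",
    "compute_wir",
    "compute_wpr",
]


def regulation_cutoff(rev_normal: float, rev_cancer: float) -> float:
    """Gene-specific fold-change cutoff from the two conditions' REVs (%).

    ``1 + sqrt(2 * (REV_n^2 + REV_c^2)) / 100``; symmetric in its arguments,
    equal to 1 in the zero-variability limit and monotone in each REV.
    """
    if rev_normal < 0 or rev_cancer < 0:
        raise ValueError("REV values must be non-negative")
    return 1.0 + np.sqrt(2.0 * (rev_normal ** 2 + rev_cancer ** 2)) / 100.0


def signed_ratio(ave_normal: float, ave_cancer: float) -> float:
    """Signed expression ratio: >= 1 for up-, <= -1 for downregulation.

    ``x = AVE_cancer / AVE_normal`` when expression rises, the negative
    reciprocal when it falls, and exactly 1 at equality (no change).
    """
    if ave_normal <= 0 or ave_cancer <= 0:
        raise ValueError("AVE values must be strictly positive")
    if ave_cancer > ave_normal:
        return ave_cancer / ave_normal
    if ave_cancer < ave_normal:
        return -ave_normal / ave_cancer
    return 1.0


def gene_pvalue(
    dataset: ExpressionDataset, normal: str, cancer: str, gene: str
) -> float:
    """Spot-Bonferroni Welch p-value for one gene between two groups.

    Per spot, a two-sided Welch (unequal-variance) t-test compares the log2
    replicate values of the two groups; the gene-level p-value is
    ``min(1, Ri * min_k p_k)``. Degenerate spots (zero variance in both
    groups and equal means) contribute p = 1.
    """
    require_valid(dataset)
    a_n = np.log2(dataset.gene_values(normal, gene))
    a_c = np.log2(dataset.gene_values(cancer, gene))
    p_spots = _welch_rows(a_n, a_c)
    return float(min(1.0, a_n.shape[0] * np.min(p_spots)))


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values for (rows, replicas) arrays."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # zero variance in both groups: identical means -> no evidence (p = 1);
    # different means -> infinitely strong evidence (p = 0)
    var0 = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if np.any(var0):
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(var0 & equal, 1.0, p)
        p = np.where(var0 & ~equal, 0.0, p)
    return np.nan_to_num(p, nan=1.0)


@dataclass
class RegulationRecord:
    """Regulation of one gene between the normal tissue and one nodule."""

    gene: str
    ave_normal: float
    ave_cancer: float
    x: float
    cut: float
    p: float
    significant: bool
    wir: float


def compute_wir(ave_normal: float, x: float, p: float) -> float:
    """Weighted individual gene regulation: AVE * sign(x) * (|x|-1) * (1-p)."""
    if abs(x) < 1:
        raise ValueError(f"signed ratio must satisfy |x| >= 1, got {x}")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    return ave_normal * np.sign(x) * (abs(x) - 1.0) * (1.0 - p)


def test_regulation(
    dataset: ExpressionDataset,
    normal: str,
    cancer: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Composite regulation call for every gene, normal -> cancer.

    Returns a frame indexed by gene with columns AVE_normal, AVE_cancer, x,
    CUT, p, significant, WIR. ``significant`` is the conjunction
    ``|x| > CUT and p < alpha``.
    """
    require_valid(dataset)
    for grp in (normal, cancer):
        if grp not in dataset.groups:
            raise KeyError(f"group {grp!r} not in dataset")

    ave_n = compute_ave(dataset, normal)
    ave_c = compute_ave(dataset, cancer)
    rev_n = compute_rev(dataset, normal)
    rev_c = compute_rev(dataset, cancer)

    x = np.where(
        ave_c > ave_n,
        ave_c / ave_n,
        np.where(ave_c < ave_n, -ave_n / ave_c, 1.0),
    )
    cut = 1.0 + np.sqrt(2.0 * (rev_n ** 2 + rev_c ** 2)) / 100.0

    # one vectorized Welch pass over all spots, then per-gene Bonferroni
    p_spots = _welch_rows(
        np.log2(dataset.group_values(normal)), np.log2(dataset.group_values(cancer))
    )
    starts = dataset.spot_offsets[:-1]
    counts = dataset.spot_counts()
    p_min = np.minimum.reduceat(p_spots, starts)
    p_gene = np.minimum(1.0, counts * p_min)

    significant = (np.abs(x) > cut) & (p_gene < alpha)
    wir = ave_n.to_numpy() * np.sign(x) * (np.abs(x) - 1.0) * (1.0 - p_gene)

    return pd.DataFrame(
        {
            "AVE_normal": ave_n,
            "AVE_cancer": ave_c,
            "x": x,
            "CUT": cut,
            "p": p_gene,
            "significant": significant,
            "WIR": wir,
        },
        index=dataset.genes,
    ).rename_axis("gene")


@dataclass
class PathwayRegulation:
    """Weighted regulation of one functional pathway."""

    pathway: str
    n_members: int
    n_quantified: int
    wpr: float  # NaN when no member is quantified

    @property
    def defined(self) -> bool:
        return self.n_quantified > 0


def compute_wpr(records: pd.DataFrame, pathway: str, members: list[str]) -> PathwayRegulation:
    """Average WIR over a pathway's quantified member genes.

    Members absent from the regulation table are counted and reported, never
    imputed; a pathway with no quantified member yields an undefined (NaN)
    WPR.
    """
    if not members:
        raise ValueError(f"pathway {pathway!r} has an empty gene set")
    members = list(dict.fromkeys(members))
    quantified = [g for g in members if g in records.index]
    wpr = float(records.loc[quantified, "WIR"].mean()) if quantified else float("nan")
    return PathwayRegulation(
        pathway=pathway,
        n_members=len(members),
        n_quantified=len(quantified),
        wpr=wpr,
    )
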