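"""Per-gene fabric statistics: AVE, REV and COR.

Three independent characteristics are attached to every quantified gene in a
sample group:

* **AVE** — average expression level: the mean over redundant spots of the
  per-spot replicate means, on the normalized linear scale (multiples of the
  array's median spot).
* **REV** — relative expression variability: a chi-square-corrected pooled
  coefficient of variation across biological replicas, in percent. The
  correction is the mid chi-square interval estimate of the unit standard
  deviation, computed on ``r = 4*Ri - 1`` degrees of freedom so that genes
  probed by few spots are not under-penalized: it runs from 2.15 for a
  single-spot gene down to 1.05 for a gene probed by 11 spots and tends to 1
  as the spot count grows.
* **COR** — expression coordination between two genes: a pooled Pearson-type
  coefficient between the log2 replicate fluctuations of all spot pairs.
  Significance is decided per pair from a t-distributed critical value at
  ``n = 4 * min(Ri, Rg)`` paired observations (|COR| >= 0.95 for two
  single-spot genes, >= 0.71 for two 2-spot genes, decreasing with spot
  count).

Low REV reads as tight homeostatic control of a gene's expression; high
|COR| as membership in a coordinated network — the two ingredients of the
gene hierarchy built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionDataset, SpotSummary, require_valid

__all__ = [
    "FabricProfile",
    "CorMatrix",
    "compute_ave",
    "rev_correction",
    "compute_rev",
    "compute_cor",
    "cor_matrix",
    "cor_significance_cutoff",
]

CALL_SYNERGISTIC = "synergistic"
CALL_ANTAGONISTIC = "antagonistic"
CALL_INDEPENDENT = "independent"
CALL_NOT_SIGNIFICANT = "not-significant"


# ---------------------------------------------------------------------------
# AVE and REV
# ---------------------------------------------------------------------------

def compute_ave(dataset: ExpressionDataset, group: str) -> pd.Series:
    """Average expression level per gene: mean over spots of per-spot means.

    With balanced replica counts this equals the grand mean of all
    ``Ri * J`` values of the gene.
    """
    require_valid(dataset)
    summary = SpotSummary.from_dataset(dataset, group)
    sums = np.add.reduceat(summary.mu, dataset.spot_offsets[:-1])
    ave = sums / dataset.spot_counts()
    return pd.Series(ave, index=dataset.genes, name="AVE")


@lru_cache(maxsize=None)
def rev_correction(Ri: int) -> float:
    """Mid chi-square interval correction for the pooled CV of a gene.

    ``0.5 * (sqrt(r / chi2(r; 0.975)) + sqrt(r / chi2(r; 0.025)))`` with
    ``r = 4*Ri - 1`` degrees of freedom, where ``chi2(r; a)`` is the
    upper-tail quantile (probability ``a`` to the *right*). Strictly
    decreasing in the spot count and -> 1 as ``Ri -> inf``: the fewer the
    spots, the more the finite-sample CV underestimates the true
    variability and the larger the correction.
    """
    Ri = int(Ri)
    if Ri < 1:
        raise ValueError(f"spot count must be >= 1, got {Ri}")
    r = 4 * Ri - 1
    lo = stats.chi2.ppf(0.025, r)   # chi2(r; 0.975): 97.5% to the right
    hi = stats.chi2.ppf(0.975, r)   # chi2(r; 0.025)
    return 0.5 * (np.sqrt(r / lo) + np.sqrt(r / hi))


def compute_rev(dataset: ExpressionDataset, group: str) -> pd.Series:
    """Relative expression variability per gene, in percent.

    ``REV_i = correction(Ri) * sqrt(mean_k (s_ik / mu_ik)^2) * 100`` on the
    normalized linear scale. Scale-free: rescaling every value of a gene
    leaves REV unchanged.
    """
    require_valid(dataset)
    if dataset.replicas_per_group < 2:
        raise ValueError("REV requires at least 2 replicas per group")
    summary = SpotSummary.from_dataset(dataset, group)
    cv2 = (summary.s / summary.mu) ** 2
    counts = dataset.spot_counts()
    pooled = np.add.reduceat(cv2, dataset.spot_offsets[:-1]) / counts
    corr = np.array([rev_correction(int(c)) for c in counts])
    return pd.Series(corr * np.sqrt(pooled) * 100.0, index=dataset.genes, name="REV")


@dataclass
class FabricProfile:
    """AVE and REV of every gene in one sample group, plus the median REV."""

    group: str
    ave: pd.Series
    rev: pd.Series
    spot_counts: pd.Series

    @property
    def median_rev(self) -> float:
        """Median REV over quantified genes — the group's reference variability."""
        return float(self.rev.median())

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset, group: str) -> "FabricProfile":
        return cls(
            group=group,
            ave=compute_ave(dataset, group),
            rev=compute_rev(dataset, group),
            spot_counts=pd.Series(dataset.spot_counts(), index=dataset.genes, name="Ri"),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "AVE": self.ave, "REV": self.rev, "Ri": self.spot_counts}
        ).rename_axis("gene")


# ---------------------------------------------------------------------------
# COR
# ---------------------------------------------------------------------------

def _log2_deviation_summaries(dataset: ExpressionDataset, group: str):
    """Per-gene building blocks of the pooled correlation.

    Returns ``(U, SS)`` where ``U[i, j]`` is the spot-summed log2 deviation of
    gene ``i`` in replica ``j`` and ``SS[i]`` the full sum of squared log2
    deviations over all spots and replicas. The pooled numerator over spot
    pairs factorizes as ``sum_j U[i, j] * U[g, j]``.
    """
    b = np.log2(dataset.group_values(group))
    counts = dataset.spot_counts()
    starts = dataset.spot_offsets[:-1]
    # gene-level log2 mean (mean of per-spot replicate means == grand mean,
    # balanced replicas)
    gene_mean = np.add.reduceat(b.mean(axis=1), starts) / counts
    d = b - np.repeat(gene_mean, counts)[:, None]
    U = np.add.reduceat(d, starts, axis=0)
    SS = np.add.reduceat((d ** 2).sum(axis=1), starts)
    return U, SS


def compute_cor(dataset: ExpressionDataset, group: str, gene_i: str, gene_g: str) -> float:
    """Pooled log2 expression correlation between two genes in one group.

    Every spot of one gene is paired with every spot of the other; the
    numerator sums the products of replicate deviations over all spot pairs
    while the denominator pools the squared deviations of each gene. Clamped
    to [-1, 1] against floating-point overshoot; NaN when either gene has
    zero variance (undefined correlation, excluded from averages).
    """
    require_valid(dataset)
    U, SS = _log2_deviation_summaries(dataset, group)
    ii = dataset.gene_index(gene_i)
    gg = dataset.gene_index(gene_g)
    if SS[ii] == 0.0 or SS[gg] == 0.0:
        return float("nan")
    if ii == gg:
        return 1.0
    num = float(U[ii] @ U[gg])
    return float(np.clip(num / np.sqrt(SS[ii] * SS[gg]), -1.0, 1.0))


@lru_cache(maxsize=None)
def cor_significance_cutoff(Ri: int, Rg: int, alpha: float = 0.05) -> float:
    """Two-sided p < alpha critical |COR| for a gene pair.

    The effective number of paired observations is ``n = 4 * min(Ri, Rg)``
    (the less-redundant gene limits the information); the critical value is
    the Pearson |r| whose t statistic hits the ``1 - alpha/2`` quantile at
    ``n - 2`` degrees of freedom. Non-increasing in ``min(Ri, Rg)``.
    """
    if Ri < 1 or Rg < 1:
        raise ValueError("spot counts must be >= 1")
    n = 4 * min(int(Ri), int(Rg))
    if n <= 2:
        raise ValueError(f"need more than 2 paired observations, got n={n}")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit ** 2))


@dataclass
class CorMatrix:
    """Pairwise coordination of all genes in one group, with significance calls.

    ``cor[i, g]`` is NaN where either gene has zero variance. Calls follow the
    per-pair cutoff: synergistic for ``COR >= cutoff``, antagonistic for
    ``COR <= -cutoff``, *independent* (experimental call, see methods) when
    ``|COR|`` lies inside a near-zero band, not-significant otherwise.
    """

    group: str
    genes: list[str]
    cor: np.ndarray
    cutoff: np.ndarray
    independence_band: float = 0.05

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def value(self, gene_i: str, gene_g: str) -> float:
        return float(self.cor[self._index[gene_i], self._index[gene_g]])

    def row(self, gene: str) -> pd.Series:
        i = self._index[gene]
        return pd.Series(self.cor[i], index=self.genes, name=gene)

    def cutoff_row(self, gene: str) -> pd.Series:
        i = self._index[gene]
        return pd.Series(self.cutoff[i], index=self.genes, name=gene)

    def call(self, gene_i: str, gene_g: str) -> str:
        c = self.value(gene_i, gene_g)
        cut = float(self.cutoff[self._index[gene_i], self._index[gene_g]])
        return self._classify(c, cut)

    def _classify(self, c: float, cut: float) -> str:
        if np.isnan(c):
            return CALL_NOT_SIGNIFICANT
        if c >= cut:
            return CALL_SYNERGISTIC
        if c <= -cut:
            return CALL_ANTAGONISTIC
        if abs(c) <= self.independence_band:
            return CALL_INDEPENDENT
        return CALL_NOT_SIGNIFICANT

    def calls_for(self, gene: str) -> pd.Series:
        i = self._index[gene]
        out = np.full(len(self.genes), CALL_NOT_SIGNIFICANT, dtype=object)
        row, cut = self.cor[i], self.cutoff[i]
        with np.errstate(invalid="ignore"):
            out[row >= cut] = CALL_SYNERGISTIC
            out[row <= -cut] = CALL_ANTAGONISTIC
            band = (np.abs(row) <= self.independence_band) & ~np.isnan(row)
            out[band & (out == CALL_NOT_SIGNIFICANT)] = CALL_INDEPENDENT
        return pd.Series(out, index=self.genes, name=gene)

    def mean_square_offdiag(self, significant_only: bool = False) -> pd.Series:
        """Mean COR^2 over defined partners g != i for every gene i.

        This is the coordination ingredient of the gene hierarchy. With
        ``significant_only`` the average is restricted to pairs beyond their
        significance cutoff (zero when a gene has none).
        """
        c2 = self.cor ** 2
        np.fill_diagonal(c2, np.nan)
        if significant_only:
            with np.errstate(invalid="ignore"):
                mask = np.abs(self.cor) >= self.cutoff
            np.fill_diagonal(mask, False)
            c2 = np.where(mask, c2, np.nan)
            n_def = np.sum(~np.isnan(c2), axis=1)
            # genes with no significant partner get coordination 0
            sums = np.nansum(c2, axis=1)
            means = np.divide(sums, n_def, out=np.zeros(len(self.genes)), where=n_def > 0)
            return pd.Series(means, index=self.genes)
        n_def = np.sum(~np.isnan(c2), axis=1)
        sums = np.nansum(c2, axis=1)
        means = np.divide(sums, n_def, out=np.full(len(self.genes), np.nan), where=n_def > 0)
        return pd.Series(means, index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        """Long-format pairwise table (upper triangle), one row per pair."""
        iu, ig = np.triu_indices(len(self.genes), k=1)
        genes = np.asarray(self.genes)
        calls = [
            self._classify(self.cor[a, b], self.cutoff[a, b]) for a, b in zip(iu, ig)
        ]
        return pd.DataFrame(
            {
                "gene_i": genes[iu],
                "gene_g": genes[ig],
                "COR": self.cor[iu, ig],
                "cutoff": self.cutoff[iu, ig],
                "call": calls,
            }
        )


def cor_matrix(
    dataset: ExpressionDataset,
    group: str,
    alpha: float = 0.05,
    independence_band: float = 0.05,
) -> CorMatrix:
    """Materialize the full COR matrix of one group.

    O(N^2) memory; intended for gene universes up to a few thousand. For a
    single gene's coordination profile use :func:`compute_cor` or
    :meth:`CorMatrix.row` on a subset.
    """
    require_valid(dataset)
    U, SS = _log2_deviation_summaries(dataset, group)
    denom = np.sqrt(np.outer(SS, SS))
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.clip((U @ U.T) / denom, -1.0, 1.0)
    cor[SS == 0.0, :] = np.nan
    cor[:, SS == 0.0] = np.nan
    np.fill_diagonal(cor, np.where(SS > 0.0, 1.0, np.nan))

    counts = dataset.spot_counts()
    pair_min = np.minimum.outer(counts, counts)
    cutoffs = {int(m): cor_significance_cutoff(int(m), int(m), alpha) for m in np.unique(pair_min)}
    cutoff = np.vectorize(cutoffs.get)(pair_min).astype(float)
    return CorMatrix(
        group=group,
        genes=list(dataset.genes),
        cor=cor,
        cutoff=cutoff,
        independence_band=independence_band,
    )
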