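"""Gene Commanding Height, Gene Master Regulator and panel selection.

The Gene Commanding Height (GCH) of gene ``i`` in a sample group combines the
two fabric ingredients into one influence score::

    GCH_i = (median_REV / REV_i) * exp(4 * mean_{g != i} COR_{ig}^2)

The first factor rewards tight transcriptional control (low REV relative to
the group's median gene); the second rewards broad expression coordination
with the rest of the transcriptome, scaled so that perfect coordination with
everything contributes e^4 ~ 54.6 and no coordination contributes 1. The top
gene of the descending-GCH hierarchy is the group's Gene Master Regulator
(GMR): the gene whose manipulation is expected to perturb that phenotype's
transcriptome the most.

A multi-nodule panel assigns one distinct GMR-like gene to every cancer
nodule, requiring its GCH in the nodule to stand far above (default 10x) the
same gene's GCH in the cancer-free tissue so that targeting it spares the
normal cells; a gene topping two nodules is kept where its GCH is larger and
the other nodule falls back to its next-in-line qualifying gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fabric import CorMatrix, FabricProfile

__all__ = [
    "GchTable",
    "PanelSelection",
    "compute_gch",
    "identify_gmr",
    "select_panel",
    "count_distinct_panels",
]


@dataclass
class GchTable:
    """Ranked GCH hierarchy of one sample group.

    ``table`` columns: gene (index), REV, transcription_control, coordination,
    GCH, rank (1-based, descending GCH). Genes with REV == 0 have unbounded
    transcription control; they are excluded from the ranked table and listed
    in ``infinite_control`` above all finite-GCH genes.
    """

    group: str
    table: pd.DataFrame
    median_rev: float
    infinite_control: list[str] = field(default_factory=list)

    def gch(self, gene: str) -> float:
        if gene in self.infinite_control:
            return float("inf")
        return float(self.table.loc[gene, "GCH"])

    def ranked_genes(self) -> list[str]:
        """All genes in hierarchy order, infinite-control genes first."""
        return self.infinite_control + self.table.index.tolist()


def compute_gch(
    fabric: FabricProfile,
    cors: CorMatrix,
    significant_only: bool = False,
) -> GchTable:
    """Build the GCH hierarchy of one group from its fabric statistics.

    ``significant_only`` restricts the coordination average to partners beyond
    their significance cutoff; the default averages COR^2 over every defined
    pair, matching the score's definition.

    Ties in GCH are broken by lower REV, then by gene symbol; the ordering is
    fully deterministic.
    """
    if list(fabric.rev.index) != list(cors.genes):
        raise ValueError("fabric profile and COR matrix cover different gene sets")
    rev = fabric.rev
    median_rev = float(rev.median())
    mean_c2 = cors.mean_square_offdiag(significant_only=significant_only)

    infinite = rev.index[rev == 0.0].tolist()
    finite = rev.index[rev > 0.0]

    control = median_rev / rev.loc[finite]
    coordination = np.exp(4.0 * mean_c2.loc[finite].fillna(0.0))
    gch = control * coordination

    table = pd.DataFrame(
        {
            "REV": rev.loc[finite],
            "transcription_control": control,
            "coordination": coordination,
            "GCH": gch,
        }
    ).rename_axis("gene")
    table = table.sort_values(
        by=["GCH", "REV", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return GchTable(
        group=cors.group,
        table=table,
        median_rev=median_rev,
        infinite_control=sorted(infinite),
    )


def identify_gmr(gch: GchTable) -> str:
    """Top gene of the hierarchy (rank 1; infinite-control genes outrank all)."""
    if gch.infinite_control:
        return gch.infinite_control[0]
    if len(gch.table) == 0:
        raise ValueError(f"empty GCH table for group {gch.group!r}")
    return str(gch.table.index[0])


@dataclass
class PanelSelection:
    """One gene per cancer nodule, each selective against the normal tissue.

    ``entries`` columns: nodule, gene (empty string when no gene qualifies),
    GCH_in_nodule, GCH_in_normal, selectivity_ratio, status and, per profiled
    group, the gene's GCH there.
    """

    normal: str
    nodules: list[str]
    min_ratio: float
    entries: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return [g for g in self.entries["gene"] if g]

    def is_complete(self) -> bool:
        return all(self.entries["status"] == "ok")


def _selectivity(gch_nodule: float, gch_normal: float) -> float:
    if math.isinf(gch_nodule):
        return float("inf")
    if gch_normal == 0.0 or math.isinf(gch_normal):
        return 0.0 if math.isinf(gch_normal) else float("inf")
    return gch_nodule / gch_normal


def select_panel(
    gch_by_group: dict[str, GchTable],
    nodules: list[str],
    normal: str,
    min_ratio: float = 10.0,
) -> PanelSelection:
    """Pick one distinct, selective high-GCH gene per nodule.

    Per nodule, candidates are the hierarchy in descending GCH order filtered
    to selectivity ratio (GCH in nodule / GCH in normal) >= ``min_ratio``.
    When one gene tops several nodules it is kept for the nodule where its
    GCH is higher (ties: the earlier nodule in ``nodules``) and the others
    take their next-in-line qualifying gene. A nodule with no qualifying gene
    gets an empty entry with a diagnostic status.
    """
    for grp in [normal, *nodules]:
        if grp not in gch_by_group:
            raise KeyError(f"group {grp!r} missing from GCH tables")
    if normal in nodules:
        raise ValueError("normal group cannot also be a nodule")

    normal_gch = gch_by_group[normal]

    def candidates(nodule: str) -> list[tuple[str, float, float, float]]:
        out = []
        tab = gch_by_group[nodule]
        for gene in tab.ranked_genes():
            g_nod = tab.gch(gene)
            try:
                g_norm = normal_gch.gch(gene)
            except KeyError:
                continue  # gene not quantified in normal tissue: no ratio
            ratio = _selectivity(g_nod, g_norm)
            if ratio >= min_ratio:
                out.append((gene, g_nod, g_norm, ratio))
        return out

    cand = {n: candidates(n) for n in nodules}
    pointer = {n: 0 for n in nodules}
    assigned: dict[str, str] = {}

    # Resolve conflicts: a gene claimed by several nodules stays where its
    # GCH is higher; losers advance to the next qualifying candidate.
    changed = True
    while changed:
        changed = False
        claims: dict[str, list[str]] = {}
        for n in nodules:
            lst, p = cand[n], pointer[n]
            while p < len(lst) and lst[p][0] in assigned and assigned[lst[p][0]] != n:
                p += 1
            pointer[n] = p
            if p < len(lst):
                claims.setdefault(lst[p][0], []).append(n)
        for gene, claimants in claims.items():
            if len(claimants) == 1:
                assigned[gene] = claimants[0]
            else:
                winner = max(
                    claimants,
                    key=lambda n: (gch_by_group[n].gch(gene), -nodules.index(n)),
                )
                assigned[gene] = winner
                changed = True

    rows = []
    for n in nodules:
        lst, p = cand[n], pointer[n]
        if p < len(lst) and assigned.get(lst[p][0]) == n:
            gene, g_nod, g_norm, ratio = lst[p]
            row = {
                "nodule": n,
                "gene": gene,
                "GCH_in_nodule": g_nod,
                "GCH_in_normal": g_norm,
                "selectivity_ratio": ratio,
                "status": "ok",
            }
            for grp, tab in gch_by_group.items():
                try:
                    row[f"GCH_{grp}"] = tab.gch(gene)
                except KeyError:
                    row[f"GCH_{grp}"] = float("nan")
        else:
            row = {
                "nodule": n,
                "gene": "",
                "GCH_in_nodule": float("nan"),
                "GCH_in_normal": float("nan"),
                "selectivity_ratio": float("nan"),
                "status": f"no gene with selectivity ratio >= {min_ratio}",
            }
        rows.append(row)
    entries = pd.DataFrame(rows)
    return PanelSelection(normal=normal, nodules=list(nodules), min_ratio=min_ratio, entries=entries)


def count_distinct_panels(n_genes: int, panel_size: int) -> int:
    """Number of distinct gene panels: C(n_genes, panel_size), exact integer.

    With ~20,000 protein-coding genes and panels of three, the count exceeds
    10^12 — the basis for the claim that two patients sharing the same
    triplet is a less than one-in-a-trillion coincidence.
    """
    if panel_size < 1 or n_genes < panel_size:
        raise ValueError(f"need n_genes >= panel_size >= 1, got ({n_genes}, {panel_size})")
    return math.comb(n_genes, panel_size)
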