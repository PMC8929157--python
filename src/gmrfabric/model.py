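"""Model/Results interface over the whole fabric pipeline.

``GMRModel`` is built from an :class:`~gmrfabric.datamodel.ExpressionDataset`
(or a long-format DataFrame) plus the group roles — which label is the
cancer-free tissue and which are cancer nodules. ``fit()`` runs the full
analysis and returns a :class:`GMRResults` carrying, per group, the fabric
profile (AVE, REV), the coordination matrix, the GCH hierarchy and its Gene
Master Regulator, per nodule the regulation table against the normal tissue,
and the multi-nodule gene panel. Pathway crossing and manipulation
predictions hang off the results object.

Example
-------
>>> from gmrfabric import SyntheticConfig, generate, GMRModel
>>> data, truth = generate(SyntheticConfig.default_planted(seed=1))
>>> res = GMRModel(data, normal="Z", nodules=["P", "Q", "M"]).fit()
>>> res.gmr["P"] == truth.hubs["P"]
True
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import ExpressionDataset, require_valid
from .fabric import CorMatrix, FabricProfile, cor_matrix
from .hierarchy import GchTable, PanelSelection, compute_gch, identify_gmr, select_panel
from .prediction import (
    PartnerPrediction,
    PathwayCross,
    cross_pathways,
    predict_manipulation,
    recommend_gmr_direction,
)
from .regulation import compute_wpr, test_regulation

__all__ = ["GMRModel", "GMRResults"]


class GMRModel:
    """Gene-hierarchy model of a replicated multi-group expression study.

    Parameters
    ----------
    dataset : ExpressionDataset
        Validated normalized expression values.
    normal : str
        Label of the cancer-free reference group.
    nodules : list of str, optional
        Cancer-nodule labels; defaults to every other group in the dataset.
    alpha : float
        Significance level for both coordination calls and regulation tests.
    min_ratio : float
        Selectivity threshold for panel membership (GCH in nodule over GCH in
        normal tissue).
    cor_mode : {"all", "significant"}
        Whether the GCH coordination factor averages COR^2 over all defined
        partners or only significantly coordinated ones.
    independence_band : float
        |COR| band for the experimental "independent" call.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        normal: str,
        nodules: list[str] | None = None,
        alpha: float = 0.05,
        min_ratio: float = 10.0,
        cor_mode: str = "all",
        independence_band: float = 0.05,
    ) -> None:
        require_valid(dataset)
        if normal not in dataset.groups:
            raise KeyError(f"normal group {normal!r} not in dataset groups {dataset.groups}")
        if nodules is None:
            nodules = [g for g in dataset.groups if g != normal]
        unknown = set(nodules) - set(dataset.groups)
        if unknown:
            raise KeyError(f"nodule group(s) not in dataset: {sorted(unknown)}")
        if normal in nodules:
            raise ValueError("normal group cannot also be a nodule")
        if cor_mode not in ("all", "significant"):
            raise ValueError("cor_mode must be 'all' or 'significant'")
        self.dataset = dataset
        self.normal = normal
        self.nodules = list(nodules)
        self.alpha = alpha
        self.min_ratio = min_ratio
        self.cor_mode = cor_mode
        self.independence_band = independence_band

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, normal: str, **kwargs) -> "GMRModel":
        """Build the model from a long-format table (sample, gene, spot, replicate, value)."""
        dataset = ExpressionDataset.from_long(frame)
        return cls(dataset, normal=normal, **kwargs)

    @property
    def groups(self) -> list[str]:
        return [self.normal, *self.nodules]

    def fit(self) -> "GMRResults":
        """Run fabric statistics, hierarchy, regulation and panel selection."""
        fabric = {g: FabricProfile.from_dataset(self.dataset, g) for g in self.groups}
        cors = {
            g: cor_matrix(
                self.dataset, g, alpha=self.alpha, independence_band=self.independence_band
            )
            for g in self.groups
        }
        gch = {
            g: compute_gch(fabric[g], cors[g], significant_only=self.cor_mode == "significant")
            for g in self.groups
        }
        gmr = {g: identify_gmr(gch[g]) for g in self.groups}
        regulation = {
            n: test_regulation(self.dataset, self.normal, n, alpha=self.alpha)
            for n in self.nodules
        }
        panel = (
            select_panel(gch, self.nodules, self.normal, min_ratio=self.min_ratio)
            if self.nodules
            else None
        )
        return GMRResults(
            model=self,
            fabric=fabric,
            cors=cors,
            gch=gch,
            gmr=gmr,
            regulation=regulation,
            panel=panel,
        )


@dataclass
class GMRResults:
    """Fitted fabric characterization of one multi-group study."""

    model: GMRModel
    fabric: dict[str, FabricProfile]
    cors: dict[str, CorMatrix]
    gch: dict[str, GchTable]
    gmr: dict[str, str]
    regulation: dict[str, pd.DataFrame]
    panel: PanelSelection | None
    _wpr_cache: dict = field(default_factory=dict, repr=False)

    # -- downstream analyses -------------------------------------------------
    def pathway_regulation(self, pathways: dict[str, list[str]], nodule: str) -> pd.DataFrame:
        """WPR of every pathway for one nodule (mean WIR over quantified members)."""
        records = self.regulation[nodule]
        rows = [compute_wpr(records, name, members) for name, members in pathways.items()]
        return pd.DataFrame(
            {
                "pathway": [r.pathway for r in rows],
                "n_members": [r.n_members for r in rows],
                "n_quantified": [r.n_quantified for r in rows],
                "WPR": [r.wpr for r in rows],
            }
        ).set_index("pathway")

    def cross_pathways(self, nodule: str, pathways: dict[str, list[str]]) -> list[PathwayCross]:
        """Pathways containing genes significantly coordinated with the nodule's GMR."""
        return cross_pathways(self.cors[nodule], self.gmr[nodule], pathways)

    def predict_manipulation(
        self, nodule: str, direction: str | None = None
    ) -> tuple[str, str, list[PartnerPrediction]]:
        """Predict partner shifts when manipulating the nodule's GMR.

        When ``direction`` is None the restoring direction is chosen from the
        GMR's own regulation record (up if the GMR is down in the nodule,
        down if up, knockdown by default otherwise). Returns the direction,
        an explanatory note and the partner predictions.
        """
        gmr = self.gmr[nodule]
        records = self.regulation[nodule]
        if direction is None:
            direction, note = recommend_gmr_direction(records.loc[gmr])
        else:
            note = "direction supplied by caller"
        preds = predict_manipulation(self.cors[nodule], gmr, direction, records)
        return direction, note, preds

    # -- presentation ---------------------------------------------------------
    def summary(self, top: int = 5) -> str:
        """Human-readable run summary: hierarchy heads, GMRs, panel, regulation."""
        m = self.model
        lines = [
            "Gene Master Regulator analysis",
            "=" * 34,
            f"genes: {m.dataset.n_genes}   replicas/group: {m.dataset.replicas_per_group}",
            f"normal: {m.normal}   nodules: {', '.join(m.nodules) or '(none)'}",
            f"alpha: {m.alpha}   panel selectivity >= {m.min_ratio}   "
            f"coordination average: {m.cor_mode} pairs",
            "",
        ]
        for grp in m.groups:
            tab = self.gch[grp].table
            lines.append(
                f"[{grp}] median REV = {self.gch[grp].median_rev:.2f}%  "
                f"GMR = {self.gmr[grp]} (GCH = {self.gch[grp].gch(self.gmr[grp]):.2f})"
            )
            head = tab.head(top)
            for gene, row in head.iterrows():
                lines.append(
                    f"    #{int(row['rank'])} {gene}: GCH {row['GCH']:.2f} "
                    f"(REV {row['REV']:.2f}%, coord {row['coordination']:.2f})"
                )
        if self.panel is not None:
            lines.append("")
            lines.append(f"panel (one selective gene per nodule, ratio >= {m.min_ratio}):")
            for _, row in self.panel.entries.iterrows():
                if row["gene"]:
                    lines.append(
                        f"    {row['nodule']}: {row['gene']}  GCH {row['GCH_in_nodule']:.2f} "
                        f"vs {row['GCH_in_normal']:.2f} in {m.normal} "
                        f"(ratio {row['selectivity_ratio']:.1f})"
                    )
                else:
                    lines.append(f"    {row['nodule']}: [none] — {row['status']}")
        for nod in m.nodules:
            rec = self.regulation[nod]
            n_sig = int(rec["significant"].sum())
            lines.append(
                f"regulation {m.normal} -> {nod}: {n_sig}/{len(rec)} genes significant "
                f"({100 * n_sig / len(rec):.1f}%)"
            )
        return "\n".join(lines)
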