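"""Pathway crossing of GMR-coordinated genes and manipulation predictions.

Once a group's Gene Master Regulator is known, two questions follow:

* which functional pathways are wired to it — i.e. contain genes whose
  expression is significantly synergistic or antagonistic with the GMR; and
* what happens to those partners when the GMR is therapeutically pushed up
  or knocked down.

The prediction rule is qualitative and deliberately minimal: a synergistic
partner moves in the GMR's direction, an antagonistic partner moves the
opposite way, and nothing is said about magnitudes. Partners whose |COR|
falls below the pair's significance cutoff receive no prediction. These are
theoretical expectations that require experimental validation; output
writers carry that caveat in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fabric import CALL_ANTAGONISTIC, CALL_SYNERGISTIC, CorMatrix

__all__ = [
    "PartnerPrediction",
    "PathwayCross",
    "cross_pathways",
    "predict_manipulation",
    "recommend_gmr_direction",
]

UP = "up"
DOWN = "down"
PREDICTION_CAVEAT = (
    "directional predictions from expression coordination; "
    "theoretical, requires experimental validation"
)


@dataclass
class PathwayCross:
    """Coordination of one pathway's members with the GMR."""

    pathway: str
    synergistic: list[str]
    antagonistic: list[str]
    n_quantified: int

    @property
    def n_coordinated(self) -> int:
        return len(self.synergistic) + len(self.antagonistic)

    @property
    def fraction_coordinated(self) -> float:
        return self.n_coordinated / self.n_quantified if self.n_quantified else 0.0


def cross_pathways(
    cors: CorMatrix, gmr: str, pathways: dict[str, list[str]]
) -> list[PathwayCross]:
    """Cross every pathway against the GMR's coordination profile.

    For each pathway the quantified members significantly synergistic or
    antagonistic with the GMR are listed; pathways are ranked by coordinated
    member count, ties broken by coordinated fraction then by name.
    """
    calls = cors.calls_for(gmr)
    quantified = set(cors.genes)
    crosses = []
    for name, members in pathways.items():
        members = [g for g in dict.fromkeys(members) if g in quantified and g != gmr]
        syn = sorted(g for g in members if calls[g] == CALL_SYNERGISTIC)
        ant = sorted(g for g in members if calls[g] == CALL_ANTAGONISTIC)
        crosses.append(
            PathwayCross(
                pathway=name,
                synergistic=syn,
                antagonistic=ant,
                n_quantified=len(members),
            )
        )
    crosses.sort(key=lambda c: (-c.n_coordinated, -c.fraction_coordinated, c.pathway))
    return crosses


@dataclass
class PartnerPrediction:
    """Predicted shift of one significantly coordinated partner gene."""

    partner: str
    relation: str           # synergistic | antagonistic
    cor: float
    current_status: str     # up | down | not-significant (vs normal tissue)
    predicted_direction: str  # up | down


def _current_status(records: pd.DataFrame | None, gene: str) -> str:
    if records is None or gene not in records.index:
        return "unquantified"
    row = records.loc[gene]
    if not bool(row["significant"]):
        return "not-significant"
    return UP if row["x"] > 0 else DOWN


def predict_manipulation(
    cors: CorMatrix,
    gmr: str,
    direction: str,
    records: pd.DataFrame | None = None,
) -> list[PartnerPrediction]:
    """Predict partner shifts under a GMR manipulation.

    Every gene significantly coordinated with the GMR gets a direction:
    synergistic partners follow the manipulation, antagonistic partners are
    pushed the opposite way. Current regulation status versus the normal
    tissue (when a regulation table is supplied) lets the reader see whether
    the predicted shift restores or aggravates the cancer profile. Flipping
    the manipulation direction flips every prediction.
    """
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if gmr not in cors.genes:
        raise KeyError(f"GMR {gmr!r} not in the coordination matrix")
    calls = cors.calls_for(gmr)
    row = cors.row(gmr)
    opposite = DOWN if direction == UP else UP
    preds = []
    for gene in cors.genes:
        if gene == gmr:
            continue
        call = calls[gene]
        if call == CALL_SYNERGISTIC:
            predicted = direction
        elif call == CALL_ANTAGONISTIC:
            predicted = opposite
        else:
            continue
        preds.append(
            PartnerPrediction(
                partner=gene,
                relation=call,
                cor=float(row[gene]),
                current_status=_current_status(records, gene),
                predicted_direction=predicted,
            )
        )
    return preds


def recommend_gmr_direction(record: pd.Series, default: str = DOWN) -> tuple[str, str]:
    """Choose the manipulation direction that restores the GMR's normal level.

    A GMR significantly downregulated in the nodule should be pushed up, an
    upregulated one knocked down. When the GMR is not significantly regulated
    there is no level to restore and the configurable default (knockdown)
    applies; the returned note says so.
    """
    if bool(record["significant"]):
        if record["x"] <= -record["CUT"]:
            return UP, "GMR downregulated in nodule; restore by overexpression"
        if record["x"] >= record["CUT"]:
            return DOWN, "GMR upregulated in nodule; restore by knockdown"
    return default, "GMR not significantly regulated; using default direction"
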