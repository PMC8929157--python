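import numpy as np
import pandas as pd
import pytest

from gmrfabric.fabric import CorMatrix, FabricProfile, cor_matrix
from gmrfabric.hierarchy import (
    GchTable,
    compute_gch,
    count_distinct_panels,
    identify_gmr,
    select_panel,
)

from conftest import random_dataset


def profile_from(revs: dict, group="Z") -> FabricProfile:
    genes = list(revs)
    return FabricProfile(
        group=group,
        ave=pd.Series(1.0, index=genes),
        rev=pd.Series(revs),
        spot_counts=pd.Series(1, index=genes),
    )


def cors_from(matrix: np.ndarray, genes: list, group="Z") -> CorMatrix:
    return CorMatrix(group=group, genes=genes, cor=matrix,
                     cutoff=np.full(matrix.shape, 0.95))


def gch_brute(rev: pd.Series, cor: np.ndarray) -> pd.Series:
    """Term-by-term reimplementation of the commanding-height formula."""
    med = rev.median()
    out = {}
    for i, gene in enumerate(rev.index):
        others = [cor[i, j] ** 2 for j in range(len(rev)) if j != i and not np.isnan(cor[i, j])]
        out[gene] = (med / rev[gene]) * np.exp(4 * np.mean(others))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# GCH
# ---------------------------------------------------------------------------

def test_gch_unity_at_median_rev_zero_coordination():
    genes = ["A", "B", "C"]
    prof = profile_from({"A": 5.0, "B": 10.0, "C": 20.0})
    cor = np.eye(3)
    gch = compute_gch(prof, cors_from(cor, genes))
    assert gch.gch("B") == pytest.approx(1.0)  # median REV, all COR = 0
    assert gch.median_rev == 10.0


def test_gch_e4_at_median_rev_full_coordination():
    genes = ["A", "B", "C"]
    prof = profile_from({"A": 5.0, "B": 10.0, "C": 20.0})
    cor = np.ones((3, 3))
    gch = compute_gch(prof, cors_from(cor, genes))
    assert gch.gch("B") == pytest.approx(np.exp(4.0))


def test_gch_matches_brute_force_on_random_group(rng):
    ds = random_dataset(rng, n_genes=10, groups=("Z",), max_spots=3)
    prof = FabricProfile.from_dataset(ds, "Z")
    cm = cor_matrix(ds, "Z")
    gch = compute_gch(prof, cm)
    expected = gch_brute(prof.rev, cm.cor)
    for gene in ds.genes:
        assert gch.gch(gene) == pytest.approx(expected[gene], rel=1e-10)


def test_gch_scale_invariance(rng):
    ds = random_dataset(rng, n_genes=8, groups=("Z",), max_spots=2)
    g0 = compute_gch(FabricProfile.from_dataset(ds, "Z"), cor_matrix(ds, "Z"))
    ds.values["Z"] *= 7.5
    g1 = compute_gch(FabricProfile.from_dataset(ds, "Z"), cor_matrix(ds, "Z"))
    pd.testing.assert_frame_equal(g0.table, g1.table, rtol=1e-10)


def test_gch_recomputes_median_after_gene_removal(rng):
    """Dropping a gene shifts the median REV; ranks must follow, not cache."""
    ds = random_dataset(rng, n_genes=9, groups=("Z",), max_spots=1)
    full = compute_gch(FabricProfile.from_dataset(ds, "Z"), cor_matrix(ds, "Z"))
    import copy

    sub = copy.deepcopy(ds)
    drop = sub.genes[-1]
    keep = [g for g in sub.genes if g != drop]
    rows = [slice(sub.spot_offsets[i], sub.spot_offsets[i + 1]) for i in range(len(sub.genes) - 1)]
    from gmrfabric.datamodel import ExpressionDataset

    sub = ExpressionDataset(
        groups=["Z"], genes=keep,
        spot_ids=sub.spot_ids[:-1],
        values={"Z": np.vstack([ds.values["Z"][r] for r in rows])},
        replicas_per_group=4,
    )
    red = compute_gch(FabricProfile.from_dataset(sub, "Z"), cor_matrix(sub, "Z"))
    expected = gch_brute(FabricProfile.from_dataset(sub, "Z").rev, cor_matrix(sub, "Z").cor)
    for gene in keep:
        assert red.gch(gene) == pytest.approx(expected[gene], rel=1e-10)
    assert red.median_rev != full.median_rev


def test_zero_rev_gene_flagged_infinite_control():
    genes = ["A", "B", "C"]
    prof = profile_from({"A": 0.0, "B": 10.0, "C": 20.0})
    cor = np.eye(3)
    cor[0, :] = cor[:, 0] = np.nan
    gch = compute_gch(prof, cors_from(cor, genes))
    assert gch.infinite_control == ["A"]
    assert "A" not in gch.table.index
    assert gch.ranked_genes()[0] == "A"
    assert identify_gmr(gch) == "A"


# ---------------------------------------------------------------------------
# GMR identification
# ---------------------------------------------------------------------------

def table_from(gch_rev: dict) -> GchTable:
    tab = pd.DataFrame(
        {"REV": {g: rv for g, (_, rv) in gch_rev.items()},
         "GCH": {g: s for g, (s, _) in gch_rev.items()}}
    ).rename_axis("gene")
    tab["transcription_control"] = np.nan
    tab["coordination"] = np.nan
    tab = tab.sort_values(["GCH", "REV", "gene"], ascending=[False, True, True], kind="mergesort")
    tab["rank"] = np.arange(1, len(tab) + 1)
    return GchTable(group="Z", table=tab, median_rev=1.0)


def test_identify_gmr_unique_maximum():
    assert identify_gmr(table_from({"A": (3, 1), "B": (9, 1), "C": (5, 1)})) == "B"


def test_identify_gmr_tie_breaks_by_lower_rev_then_symbol():
    assert identify_gmr(table_from({"A": (9, 2.0), "B": (9, 1.0)})) == "B"
    assert identify_gmr(table_from({"C": (9, 1.0), "B": (9, 1.0)})) == "B"


def test_identify_gmr_empty_table_errors():
    with pytest.raises(ValueError):
        identify_gmr(table_from({}))


def test_planted_hub_becomes_gmr(planted_run):
    _, _, truth, results = planted_run
    for nodule, hub in truth.hubs.items():
        assert results.gmr[nodule] == hub
        assert int(results.gch[nodule].table.loc[hub, "rank"]) == 1


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------

def test_panel_disjoint_tops():
    gch = {
        "Z": table_from({"A": (1, 1), "B": (1, 1), "C": (1, 1), "D": (1, 1)}),
        "P": table_from({"A": (150, 1), "B": (2, 1), "C": (2, 1), "D": (2, 1)}),
        "Q": table_from({"A": (2, 1), "B": (90, 1), "C": (2, 1), "D": (2, 1)}),
        "M": table_from({"A": (2, 1), "B": (2, 1), "C": (70, 1), "D": (2, 1)}),
    }
    panel = select_panel(gch, ["P", "Q", "M"], "Z", min_ratio=10)
    assert panel.genes == ["A", "B", "C"]
    assert panel.is_complete()


def test_panel_conflict_resolved_by_higher_gch_with_runner_up():
    gch = {
        "Z": table_from({"A": (1, 1), "B": (1, 1), "C": (1, 1)}),
        "P": table_from({"A": (150, 1), "B": (80, 1), "C": (2, 1)}),
        "Q": table_from({"A": (80, 1), "B": (2, 1), "C": (60, 1)}),
    }
    panel = select_panel(gch, ["P", "Q"], "Z", min_ratio=10)
    entries = panel.entries.set_index("nodule")
    assert entries.loc["P", "gene"] == "A"   # A's GCH is higher in P (150 > 80)
    assert entries.loc["Q", "gene"] == "C"   # Q falls back to next in line
    assert len(set(panel.genes)) == 2


def test_panel_nodule_without_qualifying_gene_is_flagged():
    gch = {
        "Z": table_from({"A": (10, 1), "B": (10, 1)}),
        "P": table_from({"A": (20, 1), "B": (15, 1)}),  # best ratio 2 < 10
    }
    panel = select_panel(gch, ["P"], "Z", min_ratio=10)
    assert panel.genes == []
    assert "no gene" in panel.entries.loc[0, "status"]


def test_panel_recovers_planted_hubs(planted_run):
    _, _, truth, results = planted_run
    assert set(results.panel.genes) == set(truth.hubs.values())
    assert results.panel.is_complete()
    # selectivity: the hub's GCH in its nodule stands far above the normal one
    assert (results.panel.entries["selectivity_ratio"] >= 10).all()


def test_panel_missing_group_errors():
    with pytest.raises(KeyError):
        select_panel({"Z": table_from({"A": (1, 1)})}, ["P"], "Z")


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n, k, expected",
    [(3, 3, 1), (5, 3, 10), (4, 2, 6)],
)
def test_count_distinct_panels_small(n, k, expected):
    assert count_distinct_panels(n, k) == expected


def test_count_distinct_panels_trillion_bound():
    assert count_distinct_panels(20000, 3) >= 10 ** 12


def test_count_distinct_panels_invalid():
    with pytest.raises(ValueError):
        count_distinct_panels(2, 3)
    with pytest.raises(ValueError):
        count_distinct_panels(5, 0)
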