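import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gmrfabric.fabric import (
    compute_ave,
    compute_cor,
    compute_rev,
    cor_matrix,
    cor_significance_cutoff,
    rev_correction,
)
from gmrfabric.synthetic import SyntheticConfig, generate

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# independent oracles: direct transcription of the defining formulas
# ---------------------------------------------------------------------------

def ave_brute(dataset, group, gene):
    block = dataset.gene_values(group, gene)
    return np.mean([spot.mean() for spot in block])


def rev_brute(dataset, group, gene):
    block = dataset.gene_values(group, gene)
    Ri = block.shape[0]
    r = 4 * Ri - 1
    corr = 0.5 * (np.sqrt(r / stats.chi2.ppf(0.025, r)) + np.sqrt(r / stats.chi2.ppf(0.975, r)))
    cv2 = [(spot.std(ddof=1) / spot.mean()) ** 2 for spot in block]
    return corr * np.sqrt(np.mean(cv2)) * 100.0


def cor_brute(dataset, group, gi, gg):
    """Direct evaluation of the pooled double sum over spot pairs (log2)."""
    bi = np.log2(dataset.gene_values(group, gi))
    bg = np.log2(dataset.gene_values(group, gg))
    Bi, Bg = bi.mean(), bg.mean()
    num = sum(
        ((bi[ki] - Bi) * (bg[kg] - Bg)).sum()
        for ki in range(bi.shape[0])
        for kg in range(bg.shape[0])
    )
    den = np.sqrt(((bi - Bi) ** 2).sum() * ((bg - Bg) ** 2).sum())
    return num / den


# ---------------------------------------------------------------------------
# AVE
# ---------------------------------------------------------------------------

def test_ave_constant_and_two_spot_examples():
    ds = make_dataset(
        {"Z": {"A": [[4, 4, 4, 4]], "B": [[2, 2, 3, 3], [6, 6, 7, 7]]}}
    )
    ave = compute_ave(ds, "Z")
    assert ave["A"] == pytest.approx(4.0)
    assert ave["B"] == pytest.approx(4.5)  # spot means 2.5 and 6.5


def test_ave_equals_grand_mean_for_balanced_replicas(rng):
    ds = random_dataset(rng, n_genes=5, groups=("Z",), max_spots=3)
    ave = compute_ave(ds, "Z")
    for gene in ds.genes:
        assert ave[gene] == pytest.approx(ds.gene_values("Z", gene).mean(), rel=1e-12)


def test_ave_unknown_group_errors(rng):
    ds = random_dataset(rng, n_genes=2, groups=("Z",))
    with pytest.raises(KeyError, match="unknown sample group"):
        compute_ave(ds, "Q")


# ---------------------------------------------------------------------------
# REV and its correction coefficient
# ---------------------------------------------------------------------------

def test_rev_correction_printed_values():
    assert round(rev_correction(1), 2) == 2.15
    assert round(rev_correction(11), 2) == 1.05


def test_rev_correction_asymptotics_and_monotonicity():
    assert rev_correction(10 ** 6) == pytest.approx(1.0, abs=1e-3)
    vals = [rev_correction(r) for r in range(1, 22)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_rev_correction_rejects_zero_spots():
    with pytest.raises(ValueError):
        rev_correction(0)


def test_rev_single_spot_oracle():
    ds = make_dataset({"Z": {"A": [[8, 10, 10, 12]]}})
    rev = compute_rev(ds, "Z")
    # CV = sqrt(8/3)/10 and the one-spot correction
    expected = rev_correction(1) * np.sqrt(8 / 3) / 10 * 100
    assert rev["A"] == pytest.approx(expected)
    assert rev["A"] == pytest.approx(35.07, abs=0.01)


def test_rev_zero_for_constant_gene_and_scale_invariance(rng):
    ds = random_dataset(rng, n_genes=4, groups=("Z",), max_spots=2)
    base = compute_rev(ds, "Z")
    ds.values["Z"] *= 2.0
    np.testing.assert_allclose(compute_rev(ds, "Z"), base, rtol=1e-12)
    flat = make_dataset({"Z": {"A": [[7, 7, 7, 7]]}})
    assert compute_rev(flat, "Z")["A"] == 0.0


def test_rev_matches_brute_force(rng):
    ds = random_dataset(rng, n_genes=8, groups=("Z",), max_spots=4)
    rev = compute_rev(ds, "Z")
    for gene in ds.genes:
        assert rev[gene] == pytest.approx(rev_brute(ds, "Z", gene), rel=1e-12)


def test_relabeling_replicas_leaves_ave_rev_unchanged(rng):
    ds = random_dataset(rng, n_genes=5, groups=("Z",), max_spots=2)
    ave0, rev0 = compute_ave(ds, "Z"), compute_rev(ds, "Z")
    perm = rng.permutation(ds.replicas_per_group)
    ds.values["Z"] = ds.values["Z"][:, perm]
    np.testing.assert_allclose(compute_ave(ds, "Z"), ave0, rtol=1e-12)
    np.testing.assert_allclose(compute_rev(ds, "Z"), rev0, rtol=1e-12)


# ---------------------------------------------------------------------------
# COR
# ---------------------------------------------------------------------------

def test_cor_self_is_one_single_spot():
    ds = make_dataset({"Z": {"A": [[1, 2, 3, 4]], "B": [[2, 4, 8, 16]]}})
    assert compute_cor(ds, "Z", "A", "A") == 1.0


def test_cor_antilinear_pair_is_minus_one():
    # log2 values of B are an affine decreasing function of log2 values of A
    a = np.array([1.0, 2.0, 4.0, 8.0])
    b = 2.0 ** (5 - np.log2(a))
    ds = make_dataset({"Z": {"A": [list(a)], "B": [list(b)]}})
    assert compute_cor(ds, "Z", "A", "B") == pytest.approx(-1.0)


def test_cor_matches_printed_double_sum(rng):
    ds = random_dataset(rng, n_genes=6, groups=("Z",), max_spots=3)
    for gi in ds.genes[:3]:
        for gg in ds.genes[3:]:
            expected = np.clip(cor_brute(ds, "Z", gi, gg), -1, 1)
            assert compute_cor(ds, "Z", gi, gg) == pytest.approx(expected, rel=1e-12)


def test_cor_single_spot_equals_standard_pearson(rng):
    ds = random_dataset(rng, n_genes=6, groups=("Z",), max_spots=1)
    for gi in ds.genes[:3]:
        for gg in ds.genes[3:]:
            bi = np.log2(ds.gene_values("Z", gi)[0])
            bg = np.log2(ds.gene_values("Z", gg)[0])
            assert compute_cor(ds, "Z", gi, gg) == pytest.approx(
                np.corrcoef(bi, bg)[0, 1], rel=1e-10
            )


def test_cor_zero_variance_gene_is_undefined():
    ds = make_dataset({"Z": {"A": [[3, 3, 3, 3]], "B": [[1, 2, 3, 4]]}})
    assert np.isnan(compute_cor(ds, "Z", "A", "B"))
    cm = cor_matrix(ds, "Z")
    assert np.isnan(cm.value("A", "A"))
    assert cm.value("B", "B") == 1.0


def test_cor_matrix_agrees_with_pairwise_and_is_symmetric(rng):
    ds = random_dataset(rng, n_genes=7, groups=("Z",), max_spots=3)
    cm = cor_matrix(ds, "Z")
    np.testing.assert_allclose(cm.cor, cm.cor.T, rtol=1e-12)
    for gi in ds.genes[:3]:
        for gg in ds.genes[3:]:
            assert cm.value(gi, gg) == pytest.approx(compute_cor(ds, "Z", gi, gg), rel=1e-12)
            assert cm.call(gi, gg) == cm.call(gg, gi)


# ---------------------------------------------------------------------------
# significance cutoffs
# ---------------------------------------------------------------------------

def test_cutoff_printed_values_and_monotonicity():
    assert round(cor_significance_cutoff(1, 1), 2) == 0.95
    assert round(cor_significance_cutoff(2, 2), 2) == 0.71
    assert cor_significance_cutoff(3, 3) < cor_significance_cutoff(2, 2)


def test_cutoff_uses_smaller_spot_count():
    assert cor_significance_cutoff(1, 5) == cor_significance_cutoff(1, 1)


def test_cutoff_rejects_invalid_spot_counts():
    with pytest.raises(ValueError):
        cor_significance_cutoff(0, 1)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=19))
def test_cutoff_non_increasing_property(r):
    assert cor_significance_cutoff(r + 1, r + 1) < cor_significance_cutoff(r, r)


def test_null_significant_fraction_near_nominal():
    """Independent genes: significant COR calls stay near the 5% level."""
    cfg = SyntheticConfig(
        n_genes=80, nodules=(), normal="Z", spot_count_probs=(1.0,), seed=5
    )
    ds, _ = generate(cfg)
    cm = cor_matrix(ds, "Z")
    iu = np.triu_indices(len(ds.genes), k=1)
    frac = np.mean(np.abs(cm.cor[iu]) >= cm.cutoff[iu])
    assert len(iu[0]) >= 2000
    assert frac <= 0.07
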