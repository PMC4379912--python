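import numpy as np
import pytest

from mtphylogeo.haplogroups import AssignmentResult, UNASSIGNED
from mtphylogeo.popstats import (
    FrequencyTable,
    amova,
    build_frequency_table,
    nei_da,
    pca_frequencies,
    wls_admixture,
)
from tests._oracles import amova_ss_from_indicators


def _table(counts, groups=None, pops=None):
    counts = np.asarray(counts)
    pops = pops or [f"P{i + 1}" for i in range(counts.shape[0])]
    return FrequencyTable(
        populations=pops,
        haplogroups=[f"H{j + 1}" for j in range(counts.shape[1])],
        counts=counts,
        groups=groups or {},
    )


# --- frequency table ------------------------------------------------------


def test_frequencies_rows_sum_to_one():
    t = _table([[3, 1], [2, 2]])
    assert np.allclose(t.frequencies.sum(axis=1), 1.0)


def test_negative_and_empty_rejected():
    with pytest.raises(ValueError):
        _table([[1, -1]])
    with pytest.raises(ValueError):
        _table([[0, 0], [1, 1]])


def test_build_frequency_table_unassigned_column():
    def res(hg, anc):
        return AssignmentResult("s", hg, [hg], 1, 1, 1, 0, anc)

    assignments = (
        [("Pop1", res("D4", "EastEurasian"))] * 3
        + [("Pop1", res(UNASSIGNED, UNASSIGNED))] * 2
        + [("Pop2", res("M45", "SouthAsian"))] * 4
    )
    t = build_frequency_table(assignments)
    assert t.haplogroups[-1] == UNASSIGNED
    assert t.counts.sum() == 9
    i, j = t.populations.index("Pop1"), t.haplogroups.index(UNASSIGNED)
    assert t.counts[i, j] == 2


def test_csv_round_trip(tmp_path):
    t = FrequencyTable(
        populations=["A", "B"],
        haplogroups=["H1", "H2"],
        counts=np.array([[3, 1], [0, 5]]),
        groups={"A": "G1", "B": "G2"},
        coordinates={"A": (10.0, 95.0), "B": (12.0, 98.0)},
    )
    path = tmp_path / "pops.csv"
    t.to_csv(str(path))
    back = FrequencyTable.from_csv(str(path))
    assert back.populations == t.populations
    assert back.haplogroups == t.haplogroups
    assert (back.counts == t.counts).all()
    assert back.groups == t.groups
    assert back.coordinates == t.coordinates


# --- PCA ------------------------------------------------------------------


def test_pca_identical_populations_zero_variance():
    t = _table([[5, 5], [5, 5]])
    r = pca_frequencies(t, 2)
    assert np.allclose(r.percent_variance, 0.0)
    assert np.allclose(r.scores[0], r.scores[1])


def test_pca_single_axis_explains_everything():
    t = _table([[9, 1], [5, 5], [1, 9]])
    r = pca_frequencies(t, 2)
    assert r.percent_variance[0] == pytest.approx(100.0)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 30, size=(10, 8))
    t = _table(counts)
    r = pca_frequencies(t, 8)
    x = t.frequencies - t.frequencies.mean(axis=0)
    lam = np.linalg.eigvalsh(x.T @ x)[::-1]
    lam = lam[lam > 1e-12]
    expected = 100.0 * lam / lam.sum()
    got = r.percent_variance[r.percent_variance > 1e-9]
    assert np.allclose(got, expected[: len(got)], atol=1e-8)
    assert r.percent_variance.sum() == pytest.approx(100.0)


def test_pca_needs_two_populations():
    with pytest.raises(ValueError):
        pca_frequencies(_table([[1, 1]]))


# --- Nei dA ----------------------------------------------------------------


def test_nei_da_identical_zero():
    t = _table([[5, 5], [10, 10]])
    assert nei_da(t, "P1", "P2") == pytest.approx(0.0)


def test_nei_da_disjoint_one():
    t = _table([[5, 0], [0, 7]])
    assert nei_da(t, "P1", "P2") == pytest.approx(1.0)


def test_nei_da_hand_value():
    t = _table([[5, 5, 0], [10, 0, 0]])
    assert nei_da(t, "P1", "P2") == pytest.approx(1 - np.sqrt(0.5))


def test_nei_da_symmetric_bounded():
    rng = np.random.default_rng(1)
    t = _table(rng.integers(1, 20, size=(4, 5)))
    for a in t.populations:
        for b in t.populations:
            d = nei_da(t, a, b)
            assert d == pytest.approx(nei_da(t, b, a))
            assert -1e-12 <= d <= 1.0


def test_nei_da_unknown_population():
    t = _table([[1, 1], [1, 1]])
    with pytest.raises(KeyError):
        nei_da(t, "P1", "nope")


# --- AMOVA ----------------------------------------------------------------


def test_amova_fixed_disjoint_groups_phi_st_one():
    t = _table(
        [[20, 0], [20, 0], [0, 20], [0, 20]],
        groups={"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"},
    )
    r = amova(t, t.groups, permutations=99, seed=1)
    assert r.phi_st == pytest.approx(1.0)
    assert r.p_ct <= 0.5


def test_amova_components_match_indicator_oracle():
    counts = np.array([[6, 2, 1], [3, 5, 2], [1, 1, 8]])
    grouping = {"P1": "G1", "P2": "G1", "P3": "G2"}
    t = _table(counts, groups=grouping)
    r = amova(t, grouping, permutations=9, seed=2)
    group_index = [[0, 1], [2]]
    ss_ag, ss_ap, ss_wp = amova_ss_from_indicators(counts, group_index)
    assert r.ss[0] == pytest.approx(ss_ag, abs=1e-9)
    assert r.ss[1] == pytest.approx(ss_ap, abs=1e-9)
    assert r.ss[2] == pytest.approx(ss_wp, abs=1e-9)


def test_amova_conservation():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 15, size=(6, 4))
    grouping = {f"P{i + 1}": ("G1" if i < 3 else "G2") for i in range(6)}
    t = _table(counts, groups=grouping)
    r = amova(t, grouping, permutations=9, seed=4)
    # sums of squares decompose the total
    pooled = counts.sum(axis=0)
    n = pooled.sum()
    ss_total = (n * n - (pooled.astype(float) ** 2).sum()) / (2 * n)
    assert sum(r.ss) == pytest.approx(ss_total, abs=1e-9)
    assert sum(r.percent) == pytest.approx(100.0, abs=1e-6)


def test_amova_requires_seed_and_groups():
    t = _table([[1, 1], [1, 1]], groups={"P1": "G1", "P2": "G1"})
    with pytest.raises(ValueError):
        amova(t, t.groups, permutations=9, seed=None)
    with pytest.raises(ValueError):
        amova(t, t.groups, permutations=9, seed=1)


# --- WLS admixture --------------------------------------------------------


def test_admixture_exact_parent():
    parental = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
    r = wls_admixture(parental[0], parental)
    assert np.allclose(r.proportions, [1.0, 0.0], atol=1e-9)
    assert r.residual_ss == pytest.approx(0.0, abs=1e-18)


def test_admixture_exact_mixture():
    parental = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
    hybrid = 0.3 * parental[0] + 0.7 * parental[1]
    r = wls_admixture(hybrid, parental)
    assert np.allclose(r.proportions, [0.3, 0.7], atol=1e-9)
    assert r.residual_ss == pytest.approx(0.0, abs=1e-15)


def test_admixture_noisy_recovery():
    rng = np.random.default_rng(8)
    parental = np.array([[0.6, 0.3, 0.1, 0.0], [0.05, 0.15, 0.4, 0.4], [0.3, 0.3, 0.2, 0.2]])
    truth = np.array([0.5, 0.5, 0.0])
    hybrid = truth @ parental + rng.normal(0, 0.01, 4)
    r = wls_admixture(hybrid, parental)
    assert np.abs(r.proportions - truth).max() < 0.05


def test_admixture_three_parent_hull_zero_residual():
    parental = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    truth = np.array([0.2, 0.3, 0.5])
    r = wls_admixture(truth @ parental, parental)
    assert r.residual_ss == pytest.approx(0.0, abs=1e-15)
    assert np.allclose(r.proportions, truth, atol=1e-9)


def test_admixture_weights_and_constraints():
    parental = np.array([[1.0, 0.0], [0.0, 1.0]])
    hybrid = np.array([1.2, -0.2])  # outside the simplex -> clipped
    r = wls_admixture(hybrid, parental, weights=np.array([2.0, 1.0]))
    assert r.proportions.min() >= 0
    assert r.proportions.sum() == pytest.approx(1.0)


def test_admixture_rank_deficient_flagged():
    parental = np.array([[0.5, 0.5], [0.5, 0.5]])
    r = wls_admixture(np.array([0.5, 0.5]), parental)
    assert r.non_unique
    assert r.residual_ss == pytest.approx(0.0, abs=1e-15)


def test_admixture_needs_two_parents():
    with pytest.raises(ValueError):
        wls_admixture(np.array([1.0]), np.array([[1.0]]))
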