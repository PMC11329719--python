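"""Kruskal-Wallis, chi-square, FDR, effect-size maps and transitions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from pdsubtypes.io import ROIMatrix
from pdsubtypes.refdata import ALL_TABLES
from pdsubtypes.rois import ALL_ROIS
from pdsubtypes.stats import (bh_fdr, characterize_clusters, chi_square_table,
                              cohens_d, effect_size_map, kruskal_wallis,
                              posthoc_pairwise, transition_table)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def oracle_kruskal(groups):
    """Direct rank-formula oracle with tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = rankdata(pooled)
    pos, H = 0, 0.0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        H += r.sum() ** 2 / len(g)
        pos += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return H / tie


class TestKruskalWallis:
    def test_hand_example(self):
        H, df, p = kruskal_wallis([1, 2], [3, 4])
        assert H == pytest.approx(2.4)
        assert df == 1

    def test_degenerate_all_identical(self):
        H, df, p = kruskal_wallis([5, 5], [5, 5, 5])
        assert H == 0.0 and p == 1.0

    def test_matches_rank_oracle(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 10, rng.integers(3, 16)).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            H, _, _ = kruskal_wallis(*groups)
            assert H == pytest.approx(oracle_kruskal(groups), abs=1e-10)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [np.nan])


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

class TestChiSquare:
    @pytest.mark.parametrize("key", sorted(ALL_TABLES, key=str))
    def test_reproduces_published_statistics(self, key):
        counts, reported = ALL_TABLES[key]
        chi2, df, p = chi_square_table(counts)
        assert chi2 == pytest.approx(reported, abs=0.005)

    def test_proportional_rows_give_zero(self):
        chi2, df, _ = chi_square_table([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_diagonal_table(self):
        chi2, df, p = chi_square_table([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# post-hoc
# ---------------------------------------------------------------------------

class TestPosthoc:
    def test_shifted_group_pairs_detected(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            groups = {1: r.normal(0, 1, 100), 2: r.normal(0, 1, 100),
                      3: r.normal(5, 1, 100)}
            pairs = {p for p, _ in posthoc_pairwise(groups, omnibus_p=1e-6)}
            hits += pairs == {(1, 3), (2, 3)}
        assert hits >= 9

    def test_non_significant_omnibus_short_circuits(self, rng):
        groups = {1: rng.normal(size=20), 2: rng.normal(size=20)}
        assert posthoc_pairwise(groups, omnibus_p=0.5) == []

    def test_two_groups_reduce_to_omnibus(self, rng):
        a = rng.normal(0, 1, 80)
        groups = {1: a, 2: a + 4.0}
        pairs = posthoc_pairwise(groups, omnibus_p=1e-9)
        assert [p for p, _ in pairs] == [(1, 2)]

    def test_categorical_pairs(self):
        groups = {1: np.array([50, 50]), 2: np.array([50, 50]),
                  3: np.array([90, 10])}
        pairs = {p for p, _ in posthoc_pairwise(groups, omnibus_p=1e-6,
                                                kind="categorical")}
        assert pairs == {(1, 3), (2, 3)}


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def oracle_bh(p):
    """Definition oracle: q_(i) = min_{j >= i} m * p_(j) / j on sorted p."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    ps = p[order]
    q_sorted = np.array([min(m * ps[j] / (j + 1) for j in range(i, m))
                         for i in range(m)])
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBhFdr:
    def test_stepup_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_definition_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 21))
            assert np.allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# effect-size maps
# ---------------------------------------------------------------------------

def _toy_population(rng, n_hc=80, n_pd=60):
    n = n_hc + n_pd
    table = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["HC"] * n_hc + ["PD"] * n_pd,
        "cohort": rng.choice(["A", "B"], n),
        "field_strength": rng.choice([1.5, 3.0], n),
        "age": rng.normal(65, 8, n),
        "etiv": rng.normal(1.5e6, 1e5, n),
    })
    values = rng.normal(2.5, 0.15, (n, 34))
    values = np.column_stack([values, rng.normal(4000, 400, (n, 7))])
    matrix = ROIMatrix(values, table["subject_id"].tolist(), list(ALL_ROIS))
    return table, matrix


class TestEffectSizeMap:
    def test_null_cluster_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, matrix = _toy_population(rng)
            hc = (table["group"] == "HC").to_numpy()
            cl = (table["group"] == "PD").to_numpy()   # same distribution
            m = effect_size_map(matrix, table, cl, hc)
            hits += len(m.significant_rois) == 0
        assert hits >= 18

    def test_planted_effect_recovered(self):
        found, d_est = 0, []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            table, matrix = _toy_population(rng, n_hc=100, n_pd=100)
            cl = (table["group"] == "PD").to_numpy()
            j = matrix.features.index("precuneus")
            matrix.values[cl, j] -= 1.2 * 0.15     # d = 1.2 in HC-sd units
            m = effect_size_map(matrix, table, cl,
                                (table["group"] == "HC").to_numpy())
            row = m.table.set_index("roi").loc["precuneus"]
            found += bool(row["significant"])
            if row["significant"]:
                d_est.append(row["d"])
        assert found == 5
        assert abs(np.mean(d_est) - 1.2) < 0.25
        assert np.mean(d_est) > 0          # positive = more atrophy

    def test_identical_groups_give_zero_d(self, rng):
        table, matrix = _toy_population(rng, n_hc=40, n_pd=40)
        matrix.values[40:] = matrix.values[:40]
        m = effect_size_map(matrix, table, (table["group"] == "PD").to_numpy(),
                            (table["group"] == "HC").to_numpy())
        assert len(m.significant_rois) == 0

    def test_requires_hc(self, rng):
        table, matrix = _toy_population(rng)
        with pytest.raises(ValueError, match="HC"):
            effect_size_map(matrix, table, (table["group"] == "PD").to_numpy(),
                            np.zeros(len(table), bool))


def test_cohens_d_pooled_convention():
    x = np.array([0.0, 1.0, 2.0])
    y = np.array([3.0, 4.0, 5.0])
    assert cohens_d(x, y) == pytest.approx(-3.0)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

class TestTransitionTable:
    def test_identical_labelings(self):
        lab = np.array([1, 1, 2, 2, 3, 3])
        tab, chi2, df, p, ari = transition_table(lab, lab)
        assert ari == pytest.approx(1.0)
        assert np.count_nonzero(tab.to_numpy()) == 3

    def test_independent_labelings_have_null_ari(self, rng):
        a = rng.integers(1, 4, 600)
        b = rng.integers(1, 4, 600)
        _, _, _, _, ari = transition_table(a, b)
        assert abs(ari) < 0.05

    def test_hand_chi_square(self):
        a = np.repeat([1, 2], 10)
        tab, chi2, df, p, ari = transition_table(a, a)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_intersection_via_subject_ids(self):
        a = np.array([1, 1, 2])
        b = np.array([1, 2, 2])
        tab, *_ = transition_table(a, b, ["s1", "s2", "s3"], ["s2", "s3", "s4"])
        assert tab.to_numpy().sum() == 2   # s2, s3 only

    def test_excluded_subjects_dropped(self):
        a = np.array([1, 0, 2, 2])
        b = np.array([1, 1, 2, 2])
        tab, *_ = transition_table(a, b)
        assert tab.to_numpy().sum() == 3


def test_characterize_clusters_smoke(small_severity_dataset):
    table, matrix, truth, subs = small_severity_dataset
    pd_tab = table[table["group"] == "PD"].reset_index(drop=True)
    names = [s.name for s in subs]
    labels = np.array([names.index(x) + 1 for x in pd_tab["true_subtype"]])
    report = characterize_clusters(pd_tab, labels)
    assert set(report.entries["test"]) == {"kruskal-wallis", "chi-square"}
    assert (report.entries["p"].between(0, 1)).all()
    # planted age gradient across severity subtypes should surface
    age_row = report.entries.set_index("variable").loc["age"]
    assert age_row["p"] < 0.05
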