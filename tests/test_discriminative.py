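"""ROC discrimination, marker selection, protein assignment, PCA, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msic.msi_core import FeatureMatrix, PeakTable
from msic.discriminative import (
    PeptideRecord,
    assign_proteins,
    compare_area_groups,
    pca_on_candidates,
    roc_per_peak,
    select_candidates,
)


def _fm(columns):
    X = np.column_stack(columns).astype(float)
    n = X.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int)])
    return FeatureMatrix(np.abs(X), coords, np.arange(X.shape[1], dtype=float))


def _auc_brute_force(a, b):
    wins = sum((bb > aa) + 0.5 * (bb == aa) for aa in a for bb in b)
    return wins / (len(a) * len(b))


class TestROC:
    def test_perfect_separation(self):
        fm = _fm([[1, 2, 3, 4, 5, 6]])
        lab = np.array(["a"] * 3 + ["b"] * 3)
        assert roc_per_peak(fm, lab, "a", "b")[0].auc == 1.0

    def test_interleaved_example(self):
        # A {1,3}, B {2,4}: 3 of 4 cross pairs favour B
        fm = _fm([[1, 3, 2, 4]])
        lab = np.array(["a", "a", "b", "b"])
        assert roc_per_peak(fm, lab, "a", "b")[0].auc == 0.75

    def test_identical_distributions(self):
        fm = _fm([[5, 7, 5, 7]])
        lab = np.array(["a", "a", "b", "b"])
        r = roc_per_peak(fm, lab, "a", "b")[0]
        assert r.auc == 0.5

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            na, nb = rng.integers(2, 30, 2)
            x = np.abs(np.round(rng.normal(2, 1, na + nb), 1))  # rounding makes ties
            lab = np.array(["a"] * na + ["b"] * nb)
            auc = roc_per_peak(_fm([x]), lab, "a", "b")[0].auc
            assert auc == _auc_brute_force(x[:na], x[na:])

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 1, 40)
        lab = np.array(["a"] * 15 + ["b"] * 25)
        ab = roc_per_peak(_fm([x]), lab, "a", "b")[0].auc
        ba = roc_per_peak(_fm([x]), lab, "b", "a")[0].auc
        assert ab + ba == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 5, 30)
        lab = np.array(["a"] * 14 + ["b"] * 16)
        a1 = roc_per_peak(_fm([x]), lab, "a", "b")[0].auc
        a2 = roc_per_peak(_fm([np.exp(x)]), lab, "a", "b")[0].auc
        assert a1 == a2

    def test_p_values_match_mann_whitney(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(5, 2, 50), 1)
        lab = np.array(["a"] * 20 + ["b"] * 30)
        r = roc_per_peak(_fm([x]), lab, "a", "b")[0]
        sp = stats.mannwhitneyu(
            np.abs(x)[20:], np.abs(x)[:20], alternative="two-sided",
            method="asymptotic",
        )
        assert r.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_small_class_rejected(self):
        fm = _fm([[1, 2, 3]])
        with pytest.raises(ValueError, match=">= 2 pixels"):
            roc_per_peak(fm, np.array(["a", "b", "b"]), "a", "b")


class TestSelection:
    def _roc(self, auc, p):
        from msic.discriminative import ROCResult

        return ROCResult(0, 1000.0, auc, p, p, 10, 10)

    def test_high_auc_low_p_selected(self):
        assert select_candidates([self._roc(0.66, 1e-5)]) != []

    def test_low_auc_selected(self):
        assert select_candidates([self._roc(0.25, 1e-6)]) != []

    def test_similarity_band_not_selected(self):
        assert select_candidates([self._roc(0.55, 1e-9)]) == []

    def test_non_significant_not_selected(self):
        assert select_candidates([self._roc(0.9, 0.5)]) == []

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            select_candidates([], auc_hi=0.4, auc_lo=0.6)


class TestProteinAssignment:
    def _peaks(self, centers):
        c = np.asarray(centers, dtype=float)
        return PeakTable(c, c - 0.4, c + 0.4)

    def test_match_within_tolerance(self):
        peps = [PeptideRecord("PEPTIDEK", 1477.76, "P1", "prot1", 50.0)]
        matches, _ = assign_proteins(self._peaks([1477.80]), peps)
        assert len(matches) == 1
        assert matches.iloc[0]["delta_mz"] == pytest.approx(0.04)

    def test_exact_boundary_rejected(self):
        peps = [PeptideRecord("PEPTIDEK", 1477.65, "P1", "prot1", 50.0)]
        matches, _ = assign_proteins(self._peaks([1477.80]), peps, tol_da=0.15)
        assert len(matches) == 0

    def test_single_peptide_protein_not_identified(self):
        peps = [
            PeptideRecord("AAAK", 1000.00, "P1", "prot1", 40.0),
            PeptideRecord("CCCK", 1500.00, "P2", "prot2", 40.0),
            PeptideRecord("DDDK", 1600.00, "P2", "prot2", 40.0),
        ]
        _, proteins = assign_proteins(self._peaks([1000.0, 1500.0, 1600.0]), peps)
        ident = proteins.set_index("accession")["identified"]
        assert not ident["P1"] and ident["P2"]

    def test_one_peak_cannot_identify_protein(self):
        # two peptides of one protein both near a single peak
        peps = [
            PeptideRecord("AAAK", 1000.02, "P1", "prot1", 40.0),
            PeptideRecord("CCCK", 1000.05, "P1", "prot1", 60.0),
        ]
        matches, proteins = assign_proteins(self._peaks([1000.0]), peps)
        assert len(matches) == 1
        assert not proteins["identified"].any()

    def test_tie_broken_by_highest_score(self):
        peps = [
            PeptideRecord("LOWK", 1000.05, "P1", "prot1", 20.0),
            PeptideRecord("HIGHK", 999.95, "P2", "prot2", 35.0),
        ]
        matches, _ = assign_proteins(self._peaks([1000.0]), peps)
        assert matches.iloc[0]["sequence"] == "HIGHK"

    def test_smallest_delta_beats_score(self):
        peps = [
            PeptideRecord("NEARK", 1000.01, "P1", "prot1", 20.0),
            PeptideRecord("FARK", 1000.10, "P2", "prot2", 90.0),
        ]
        matches, _ = assign_proteins(self._peaks([1000.0]), peps)
        assert matches.iloc[0]["sequence"] == "NEARK"

    def test_input_order_irrelevant(self):
        rng = np.random.default_rng(4)
        peps = [
            PeptideRecord(f"SEQ{i}K", 1000.0 + i + rng.uniform(-0.05, 0.05),
                          f"P{i % 3}", f"prot{i % 3}", float(rng.uniform(20, 80)))
            for i in range(12)
        ]
        peaks = self._peaks(np.arange(1000.0, 1012.0))
        a, pa = assign_proteins(peaks, peps)
        b, pb = assign_proteins(peaks, peps[::-1])
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(pa, pb)

    def test_empty_peptide_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_proteins(self._peaks([1000.0]), [])


class TestPCA:
    def test_collinear_data_has_single_component(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([2 * t, -t, 3 * t])
        res = pca_on_candidates(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        res = pca_on_candidates(X)
        ref = PCA().fit(X)
        np.testing.assert_allclose(
            res.explained_variance_ratio[:6], ref.explained_variance_ratio_, atol=1e-9
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        res = pca_on_candidates(X)
        for j in range(res.loadings.shape[1]):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 5))
        res = pca_on_candidates(X)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, X - X.mean(axis=0), atol=1e-9
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca_on_candidates(np.zeros((10, 3)))


def _balanced_2x2(values):
    rows = []
    for (g, c), vs in values.items():
        rows += [dict(group=g, region_class=c, percent=v) for v in vs]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_textbook_balanced_example_exact(self):
        # cell means 2, 3, 6, 10 with unit spreads: hand-computed sums of
        # squares SS_A = 90.75, SS_B = 18.75, SS_AB = 6.75, SSE = 8 (df 8)
        table = _balanced_2x2(
            {
                ("a", "x"): [1, 2, 3],
                ("a", "y"): [2, 3, 4],
                ("b", "x"): [5, 6, 7],
                ("b", "y"): [9, 10, 11],
            }
        )
        an = compare_area_groups(table)
        assert an.loc["group", "sum_sq"] == pytest.approx(90.75, abs=1e-9)
        assert an.loc["region_class", "sum_sq"] == pytest.approx(18.75, abs=1e-9)
        assert an.loc["group:region_class", "sum_sq"] == pytest.approx(6.75, abs=1e-9)
        assert an.loc["residual", "sum_sq"] == pytest.approx(8.0, abs=1e-9)
        assert an.loc["group", "F"] == pytest.approx(90.75, abs=1e-9)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(100):
            table = _balanced_2x2(
                {
                    (g, c): rng.normal(10, 2, 4).tolist()
                    for g in "ab"
                    for c in "xy"
                }
            )
            ps.append(compare_area_groups(table).loc["region_class", "p"])
        assert 0.3 < np.mean(ps) < 0.7

    def test_planted_class_effect_detected(self):
        # class shift of 3 within-cell SDs at n = 7 per cell
        rng = np.random.default_rng(9)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            table = _balanced_2x2(
                {
                    (g, c): (rng.normal(10 + (3 if c == "y" else 0), 1, 7)).tolist()
                    for g in "ab"
                    for c in "xy"
                }
            )
            hits += compare_area_groups(table).loc["region_class", "p"] < 0.05
        assert hits / n_sim >= 0.95

    def test_empty_cell_rejected(self):
        table = _balanced_2x2(
            {("a", "x"): [1, 2], ("a", "y"): [2, 3], ("b", "x"): [4, 5]}
        )
        with pytest.raises(ValueError, match="cell"):
            compare_area_groups(table)
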