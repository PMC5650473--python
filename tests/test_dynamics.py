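"""Clustering, trough agglomeration, early risers, motifs, enrichment."""

import math
import re
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from primmus.dynamics import (agglomerate_by_trough, choose_k_wss,
                              classify_early_risers, compare_early_late,
                              fisher_enrichment, kmeans_cluster, motif_match,
                              normalize_sites_to_protein, prepare_profiles,
                              residue_frequencies)
from primmus.quant import replicate_median_profile

MITO = ["Pro", "PM1", "PM2", "Ana"]


def _blobs(rng, centers, n_per=40, sd=0.3):
    X = np.vstack([c + rng.normal(0, sd, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    idx = [f"P{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), labels


class TestChooseK:
    def test_three_separated_groups(self):
        rng = np.random.default_rng(0)
        prof, _ = _blobs(rng, [np.zeros(4), np.full(4, 5.0),
                               np.array([0, 5, 5, 0.0])])
        k, wss = choose_k_wss(prof, range(1, 9), seed=0)
        assert k == 3
        assert all(wss[a] >= wss[b] for a, b in zip(sorted(wss), sorted(wss)[1:]))

    def test_identical_rows_select_one(self):
        prof = pd.DataFrame(np.ones((30, 4)))
        k, wss = choose_k_wss(prof, range(1, 6), seed=0)
        assert k == 1
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in wss.values())

    def test_k_range_exceeding_rows_rejected(self):
        prof = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            choose_k_wss(prof, range(1, 10), seed=0)


class TestKMeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(20, 4)))
        a = kmeans_cluster(prof, 1, seed=0)
        assert np.allclose(a.centroids.iloc[0], prof.mean(axis=0))

    def test_antipodal_groups_perfectly_separated(self):
        rng = np.random.default_rng(2)
        prof, truth = _blobs(rng, [np.full(4, 3.0), np.full(4, -3.0)], sd=0.2)
        a = kmeans_cluster(prof, 2, seed=0)
        assert adjusted_rand_score(truth, a.labels.to_numpy()) == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        prof, _ = _blobs(rng, [np.zeros(4), np.full(4, 4.0)])
        a = kmeans_cluster(prof, 2, seed=0)
        b = kmeans_cluster(prof.iloc[::-1], 2, seed=0)
        pd.testing.assert_series_equal(a.labels.sort_index(),
                                       b.labels.sort_index())

    def test_best_of_restarts_no_worse_than_single(self):
        rng = np.random.default_rng(4)
        prof, _ = _blobs(rng, [np.zeros(4), np.full(4, 2.0),
                               np.array([2.0, 0, 2, 0])], n_per=25)
        multi = kmeans_cluster(prof, 3, seed=0, n_restarts=20)
        single = kmeans_cluster(prof, 3, seed=1, n_restarts=1)
        assert multi.wss <= single.wss + 1e-9

    def test_missing_values_rejected(self):
        prof = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            kmeans_cluster(prof, 1, seed=0)


class TestAgglomerateByTrough:
    def _assignment(self, median):
        prof = prepare_profiles(median)
        return kmeans_cluster(prof, k=len(median) // 2 or 1, seed=0)

    def test_earliest_drop_labels(self):
        median = pd.DataFrame(
            [[1, 0.4, 0.35, 0.3]] * 2 + [[1, 1, 1, 0.3]] * 2
            + [[1, 1.6, 1.8, 2.0]] * 2,
            index=[f"P{i}" for i in range(6)], columns=MITO)
        assignment = kmeans_cluster(prepare_profiles(median), 3, seed=0)
        groups = agglomerate_by_trough(assignment, median)
        by_group = groups.set_index("group")["n_proteins"].to_dict()
        assert by_group.get("PM1") == 2 and by_group.get("Ana") == 2
        # the increasing cluster is removed (empty group label)
        assert by_group.get("") == 2

    def test_no_decreasing_clusters_raises(self):
        median = pd.DataFrame([[1, 1.5, 1.8, 2.0]] * 4,
                              index=[f"P{i}" for i in range(4)], columns=MITO)
        assignment = kmeans_cluster(prepare_profiles(median), 1, seed=0)
        with pytest.raises(ValueError):
            agglomerate_by_trough(assignment, median)

    def test_planted_troughs_recovered(self, mitotic_data):
        merged, truth = mitotic_data
        median = replicate_median_profile(merged)
        planted = truth.index[truth["trough"] != ""]
        median = median.loc[median.index.intersection(planted)]
        profiles = prepare_profiles(median)
        assignment = kmeans_cluster(profiles, 6, seed=0)
        groups = agglomerate_by_trough(assignment, median.loc[profiles.index])
        assigned = assignment.labels.map(groups["group"])
        ok = assigned[assigned != ""]
        agreement = (ok == truth.loc[ok.index, "trough"]).mean()
        assert agreement >= 0.9
        assert set(groups.loc[groups["group"] != "", "group"]) == {"PM1", "PM2", "Ana"}


class TestEarlyRisers:
    def test_planted_classification_accuracy(self, phospho_data):
        _, quant, truth = phospho_data
        med = replicate_median_profile(quant)
        significant = (med.max(axis=1) / med.min(axis=1)) > 2.0
        labels = classify_early_risers(quant, significant)
        early_true = truth["class_label"] == "early_riser"
        late_true = truth["class_label"] == "late_riser"
        sens = (labels[early_true] == "early").mean()
        specificity = (labels[late_true] == "late").mean()
        assert 0.5 * (sens + specificity) >= 0.9

    def test_flat_sites_excluded(self, phospho_data):
        _, quant, truth = phospho_data
        med = replicate_median_profile(quant)
        significant = (med.max(axis=1) / med.min(axis=1)) > 2.0
        labels = classify_early_risers(quant, significant)
        flat = truth["class_label"] == "flat"
        assert (labels[flat] == "excluded").mean() > 0.95

    def test_missing_g2_unclassifiable(self):
        cols = pd.MultiIndex.from_product([["G1", "S", "G2", "M"], ["r1", "r2"]],
                                          names=["fraction", "replicate"])
        q = pd.DataFrame([[1, 1.1, 1, 0.9, np.nan, np.nan, 8, 8.2]],
                         index=["S1"], columns=cols)
        labels = classify_early_risers(q, pd.Series([True], index=["S1"]))
        assert labels["S1"] == "unclassifiable"


class TestResidueAndMotif:
    def test_residue_fraction_examples(self):
        sites = pd.DataFrame({"amino_acid": list("SSSST")})
        freq = residue_frequencies(sites)
        assert freq["S"] == 0.8 and freq["T"] == 0.2 and freq["Y"] == 0.0
        assert freq.sum() == pytest.approx(1.0)

    def test_all_tyrosine(self):
        freq = residue_frequencies(pd.DataFrame({"amino_acid": ["Y", "Y"]}))
        assert freq["Y"] == 1.0

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            residue_frequencies(pd.DataFrame({"amino_acid": ["S", "A"]}))

    def test_motif_examples(self):
        # TPX2 S185-like context: S-P-E-K
        w = "AAAAAAASPEKAAAA"[:15]
        out = motif_match(w)
        assert out == {"proline_directed": True, "full_cdk_consensus": True}
        assert motif_match("AAAAAAASAEKAAAA"[:15])["proline_directed"] is False
        out = motif_match("AAAAAAATPEQAAAA"[:15])
        assert out["proline_directed"] and not out["full_cdk_consensus"]

    def test_malformed_window_rejected(self):
        with pytest.raises(ValueError):
            motif_match("SHORT")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY_", min_size=15, max_size=15))
    @settings(deadline=None, max_examples=500)
    def test_matches_regex_oracle(self, window):
        out = motif_match(window)
        assert out["proline_directed"] == bool(
            re.match(r"^.{7}[ST]P", window))
        assert out["full_cdk_consensus"] == bool(
            re.match(r"^.{7}[ST]P.[KR]", window))


class TestCompareEarlyLate:
    def _quant(self, values):
        cols = pd.MultiIndex.from_product([["M"], ["r1"]],
                                          names=["fraction", "replicate"])
        return pd.DataFrame(np.asarray(values, float)[:, None],
                            index=[f"S{i}" for i in range(len(values))],
                            columns=cols)

    def test_planted_early_risers_have_higher_m_ratio(self, phospho_data):
        _, quant, truth = phospho_data
        med = replicate_median_profile(quant)
        significant = (med.max(axis=1) / med.min(axis=1)) > 2.0
        labels = classify_early_risers(quant, significant)
        out = compare_early_late(quant, labels)
        assert out.attrs["difference"] > 0

    def test_identical_groups_zero_difference(self):
        q = self._quant([2.0, 2.0, 2.0, 2.0])
        labels = pd.Series(["early", "early", "late", "late"], index=q.index)
        out = compare_early_late(q, labels)
        assert out.attrs["difference"] == pytest.approx(0.0)

    def test_single_site_group_flagged(self):
        q = self._quant([4.0, 2.0, 2.0])
        labels = pd.Series(["early", "late", "late"], index=q.index)
        out = compare_early_late(q, labels)
        assert math.isnan(out.loc["early", "sem"])

    def test_empty_group_rejected(self):
        q = self._quant([2.0, 2.0])
        labels = pd.Series(["late", "late"], index=q.index)
        with pytest.raises(ValueError):
            compare_early_late(q, labels)


def _two_sided_fisher_oracle(a, b, c, d):
    """Exhaustive two-sided hypergeometric p by enumeration over the margin."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))
    p_obs = pmf(a)
    # the conventional relative guard for pmf ties
    return sum(p for x in range(lo, hi + 1)
               if (p := pmf(x)) <= p_obs * (1 + 1e-7))


class TestFisherEnrichment:
    def _run_table(self, a, b, c, d):
        bg = [f"x{i}" for i in range(a + b + c + d)]
        cand = bg[:a + b]
        labelled = bg[:a] + bg[a + b:a + b + c]
        out = fisher_enrichment(cand, bg, {"L": labelled})
        return out.loc["L"]

    def test_perfect_association(self):
        row = self._run_table(10, 0, 0, 10)
        assert row["p_value"] == pytest.approx(2 / math.comb(20, 10))

    def test_candidate_equals_background(self):
        bg = [f"x{i}" for i in range(10)]
        out = fisher_enrichment(bg, bg, {"L": bg[:5]})
        assert out.loc["L", "p_value"] == pytest.approx(1.0)

    def test_depletion_has_odds_below_one(self):
        row = self._run_table(0, 10, 10, 10)
        assert row["odds_ratio"] < 1.0

    def test_candidate_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["a"], ["b"], {"L": ["b"]})

    def test_matches_enumeration_oracle_small_tables(self):
        # all 2x2 tables with total <= 12 (margins <= 12)
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or a + b == n:
                            continue  # empty candidate or background==candidate
                        row = self._run_table(a, b, c, d)
                        oracle = _two_sided_fisher_oracle(a, b, c, d)
                        assert row["p_value"] == pytest.approx(oracle, rel=1e-9)


class TestSiteProteinNormalisation:
    def _site_quant(self, values):
        cols = pd.MultiIndex.from_product([["G1", "M"], ["r1"]],
                                          names=["fraction", "replicate"])
        return pd.DataFrame(np.asarray(values, float),
                            index=["S1"], columns=cols)

    def test_divides_by_protein_ratio(self):
        q = self._site_quant([[1.0, 4.0]])
        prot = pd.DataFrame([[1.0, 2.0]], index=["P1"], columns=["G1", "M"])
        out, flag = normalize_sites_to_protein(q, prot,
                                               pd.Series({"S1": "P1"}))
        assert out.loc["S1", ("M", "r1")] == pytest.approx(2.0)
        assert flag["S1"]

    def test_missing_protein_passthrough_flagged(self):
        q = self._site_quant([[1.0, 4.0]])
        prot = pd.DataFrame([[1.0, 2.0]], index=["OTHER"], columns=["G1", "M"])
        out, flag = normalize_sites_to_protein(q, prot,
                                               pd.Series({"S1": "P1"}))
        assert out.loc["S1", ("M", "r1")] == pytest.approx(4.0)
        assert not flag["S1"]

    def test_zero_protein_ratio_rejected(self):
        q = self._site_quant([[1.0, 4.0]])
        prot = pd.DataFrame([[1.0, 0.0]], index=["P1"], columns=["G1", "M"])
        with pytest.raises(ValueError):
            normalize_sites_to_protein(q, prot, pd.Series({"S1": "P1"}))
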