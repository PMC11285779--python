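import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from jawmorph import (lda_jackknife, permanova_oneway, permanova_pairwise,
                      standardized_characters, euclidean_distances, pcoa)
from jawmorph.inference import GroupSizeError, adjust_pvalues


def _centroid_F(X, labels):
    """Independent pseudo-F oracle computed from group centroids."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    groups = sorted(set(labels))
    n, g = len(X), len(groups)
    ss_between = sum(((X[labels == gr].mean(axis=0) - grand) ** 2).sum()
                     * (labels == gr).sum() for gr in groups)
    ss_within = sum(((X[labels == gr] - X[labels == gr].mean(axis=0)) ** 2).sum()
                    for gr in groups)
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def test_pseudo_f_matches_centroid_oracle_and_skbio():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(18, 4))
    labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
    res = permanova_oneway(X, labels, 99, seed=1)
    assert res.pseudo_F == pytest.approx(_centroid_F(X, labels), abs=1e-10)
    dm = DistanceMatrix(
        np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)),
        ids=[str(i) for i in range(18)])
    ref = skbio_permanova(dm, grouping=list(labels), permutations=0)
    assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), abs=1e-10)


def test_exhaustive_small_sample_matches_enumeration_oracle():
    """For 3|3 groups the permutation p is the exact fraction of the 20
    distinct splits with F >= observed, via an independent enumeration."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 3))
    X[3:] += 1.5
    labels = np.array(["a"] * 3 + ["b"] * 3)
    res = permanova_oneway(X, labels, "exhaustive", seed=0)
    assert res.exhaustive and res.n_permutations == 20
    F_all = []
    for combo in itertools.combinations(range(6), 3):
        lab = np.array(["b"] * 6, dtype=object)
        lab[list(combo)] = "a"
        F_all.append(_centroid_F(X, lab))
    F_obs = _centroid_F(X, labels)
    expected_p = np.mean(np.asarray(F_all) >= F_obs - 1e-12)
    assert res.p_raw == pytest.approx(expected_p, abs=1e-12)


def test_maximal_separation_hits_p_floor():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, size=(10, 2)),
                   rng.normal(100, 1, size=(10, 2))])
    labels = ["a"] * 10 + ["b"] * 10
    res = permanova_oneway(X, labels, 99, seed=3)
    assert not res.exhaustive
    assert res.p_raw == pytest.approx(1 / 100)


def test_permanova_identical_on_pco_axes_and_characters(balanced30):
    """Full-space PCo scores preserve Euclidean geometry, so PERMANOVA is
    identical on scores and on the z-corrected characters."""
    std = standardized_characters(balanced30)
    coords = pcoa(euclidean_distances(std)).coordinates
    labels = balanced30.labels("guild")
    a = permanova_oneway(std.values, labels, 199, seed=9)
    b = permanova_oneway(coords, labels, 199, seed=9)
    assert a.pseudo_F == pytest.approx(b.pseudo_F, abs=1e-10)
    assert a.p_raw == b.p_raw


def test_p_invariant_to_label_names_and_specimen_order():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(14, 3))
    labels = np.array(["a"] * 7 + ["b"] * 7)
    base = permanova_oneway(X, labels, 199, seed=4)
    renamed = permanova_oneway(
        X, np.where(labels == "a", "zzz", "mmm"), 199, seed=4)
    assert base.p_raw == renamed.p_raw
    # in the exhaustive regime the p is an exact fraction, hence invariant
    # to specimen order as well
    order = rng.permutation(14)
    small = rng.normal(size=(8, 3))
    small_labels = np.array(["a"] * 4 + ["b"] * 4)
    a = permanova_oneway(small, small_labels, "exhaustive")
    order8 = rng.permutation(8)
    b = permanova_oneway(small[order8], small_labels[order8], "exhaustive")
    assert a.p_raw == b.p_raw
    reordered = permanova_oneway(X[order], labels[order], 199, seed=4)
    assert base.pseudo_F == pytest.approx(reordered.pseudo_F, abs=1e-10)


def test_small_group_raises(balanced30):
    labels = list(balanced30.labels("guild"))
    labels[0] = "Singleton"
    with pytest.raises(GroupSizeError, match="Singleton"):
        permanova_oneway(standardized_characters(balanced30).values, labels,
                         99, seed=1, min_group_size=2)


def test_pairwise_counts_and_corrections(balanced30):
    std = standardized_characters(balanced30)
    table = permanova_pairwise(std.values, balanced30.labels("guild"),
                               99, seed=2)
    assert len(table) == 15  # C(6,2)
    tested = table[~table["skipped"]]
    assert (tested["p_bonferroni"] >= tested["p_bh"] - 1e-12).all()
    assert (tested["p_bh"] >= tested["p_raw"] - 1e-12).all()


def test_pairwise_skips_undersized_pairs(balanced30):
    labels = np.asarray(balanced30.labels("guild"), dtype=object)
    labels[labels == "Cut"] = ["Cut", "Cut", "Rare", "Rare", "Cut"]
    table = permanova_pairwise(standardized_characters(balanced30).values,
                               labels, 99, seed=2, min_group_size=3)
    skipped = table[table["skipped"]]
    assert (skipped[["group_A", "group_B"]].isin(["Rare"]).any(axis=1)).all()
    assert len(skipped) == 6  # Rare against the 6 other groups


def test_pvalue_adjustment_hand_examples():
    assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx(
        [0.04, 0.04, 0.04, 0.04])
    p = [0.02] + [1.0] * 9
    assert adjust_pvalues(p, "bonferroni")[0] == pytest.approx(0.2)


def test_lda_perfect_separability():
    rng = np.random.default_rng(13)
    X = np.vstack([rng.normal(0, 1, size=(10, 3)),
                   rng.normal(100, 1, size=(10, 3))])
    res = lda_jackknife(X, ["a"] * 10 + ["b"] * 10)
    assert res.overall_jackknife_rate == 1.0
    assert res.confusion_matrix.to_numpy().sum() == 20
    assert list(res.confusion_matrix.sum(axis=1)) == [10, 10]


def test_lda_chance_level_under_label_permutation():
    """With labels independent of the data, jackknife recovery sits at the
    1/g chance level."""
    rng = np.random.default_rng(17)
    X = rng.normal(size=(24, 4))
    labels = np.array(["a", "b", "c"] * 8)
    rates = []
    for _ in range(200):
        rates.append(lda_jackknife(
            X, rng.permutation(labels)).overall_jackknife_rate)
    mean = np.mean(rates)
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(mean - 1 / 3) < 3 * max(se, 0.01)


def test_lda_direction_matches_fisher_closed_form():
    rng = np.random.default_rng(19)
    Xa = rng.normal(0, 1, size=(15, 4))
    Xb = rng.normal(1, 1, size=(15, 4))
    X = np.vstack([Xa, Xb])
    y = ["a"] * 15 + ["b"] * 15
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    clf = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5]).fit(X, y)
    pooled = (np.cov(Xa, rowvar=False) * 14 +
              np.cov(Xb, rowvar=False) * 14) / 28
    fisher = np.linalg.solve(pooled, Xb.mean(0) - Xa.mean(0))
    w = clf.coef_.ravel()
    cos = w @ fisher / (np.linalg.norm(w) * np.linalg.norm(fisher))
    assert cos > 0.999


def test_lda_excludes_undersized_classes():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(13, 3))
    X[6:12] += 10
    labels = ["a"] * 6 + ["b"] * 6 + ["rare"]
    res = lda_jackknife(X, labels, min_class_size=3)
    assert res.excluded_classes == ["rare"]
    assert res.confusion_matrix.shape == (2, 2)
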