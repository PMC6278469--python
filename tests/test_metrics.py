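"""Ranking statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import matthews_corrcoef as sk_mcc

from efolearn import (
    ClusterDistribution,
    ConfusionMatrix,
    LinearModel,
    asymmetry_index,
    classification_metrics,
    cluster_distribution,
    confusion_from_ranking,
    enrichment_factor,
    evaluate_ranking,
    quality,
    rank,
    rank_scores,
)
from efolearn.metrics import top_fraction_size

from conftest import random_ranking


# ------------------------------------------------------------------- oracles
def ef_oracle(labels_in_order, top_fraction):
    """Literal count-and-divide enrichment factor over the ranked prefix."""
    N = len(labels_in_order)
    P = sum(labels_in_order)
    m = min(N, max(1, int(np.floor(top_fraction * N + 0.5))))
    h = sum(labels_in_order[:m])
    return (h / m) / (P / N)


def cluster_counts_oracle(labels_in_order, cluster_size):
    out = []
    for start in range(0, len(labels_in_order), cluster_size):
        out.append(sum(labels_in_order[start : start + cluster_size]))
    return out


def all_rankings(n):
    """Every label arrangement of a ranking of n instances."""
    for labels in itertools.product((0, 1), repeat=n):
        yield rank_scores(
            [str(i) for i in range(n)], -np.arange(n, dtype=float), labels
        )


# ---------------------------------------------------------------------- rank
def test_rank_sorts_descending_with_stable_ties():
    t_ids = ["r0", "r1", "r2"]
    r = rank_scores(t_ids, [3.0, 1.0, 2.0], [1, 0, 0])
    assert r.ordered_ids == ["r0", "r2", "r1"]
    # all-tied scores keep original row order
    r_tied = rank_scores(t_ids, [0.0, 0.0, 0.0], [1, 0, 0])
    assert r_tied.ordered_ids == t_ids


def test_rank_on_table_errors_for_unknown_variable(tiny_table):
    m = LinearModel(variables=["nope"], coefficients=[1.0])
    with pytest.raises(KeyError, match="nope"):
        rank(tiny_table, m)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_monotone_transform_preserves_order(seed):
    rng = np.random.default_rng(seed)
    r = random_ranking(rng)
    g = lambda s: np.exp(0.5 * s) + 3.0  # strictly increasing
    r2 = rank_scores(r.ordered_ids, g(r.scores), r.labels)
    assert r2.ordered_ids == r.ordered_ids


# ------------------------------------------------------------------------ EF
def test_ef_balanced_perfect_ranking_ceiling():
    labels = [1] * 50 + [0] * 50
    r = rank_scores([str(i) for i in range(100)], -np.arange(100.0), labels)
    assert enrichment_factor(r, 0.05) == pytest.approx(2.0)


def test_ef_proportional_prefix():
    labels = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0]  # 1 positive in top 2, P=5
    r = rank_scores([str(i) for i in range(10)], -np.arange(10.0), labels)
    assert enrichment_factor(r, 0.2) == pytest.approx((1 / 2) / (5 / 10))


def test_ef_requires_a_positive():
    r = rank_scores(["a", "b"], [1.0, 0.0], [0, 0])
    with pytest.raises(ValueError, match="positive"):
        enrichment_factor(r, 0.5)


def test_ef_matches_oracle_on_200_random_rankings():
    rng = np.random.default_rng(123)
    for _ in range(200):
        r = random_ranking(rng, n_max=50)
        f = float(rng.uniform(0.01, 1.0))
        assert enrichment_factor(r, f) == pytest.approx(
            ef_oracle(r.labels.tolist(), f), abs=1e-12
        )


def test_ef_bound_over_all_prefix_sizes():
    rng = np.random.default_rng(9)
    for _ in range(50):
        r = random_ranking(rng, n_max=30)
        N, P = r.n_total, r.n_positive
        for m in range(1, N + 1):
            ef = enrichment_factor(r, m / N)
            m_used = top_fraction_size(N, m / N)
            assert 0.0 <= ef <= min(m_used, P) * N / (m_used * P) + 1e-12


# ------------------------------------------------------------------ clusters
def test_cluster_counts_and_percentages():
    labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    r = rank_scores([str(i) for i in range(10)], -np.arange(10.0), labels)
    d = cluster_distribution(r, 5)
    assert d.counts.tolist() == [3, 0]
    assert d.percentages.tolist() == [60.0, 0.0]


def test_last_cluster_uses_its_own_size():
    labels = [0, 0, 0, 0, 0, 0, 1]
    r = rank_scores([str(i) for i in range(7)], -np.arange(7.0), labels)
    d = cluster_distribution(r, 3)
    assert d.sizes.tolist() == [3, 3, 1]
    assert d.percentages[-1] == pytest.approx(100.0)
    assert d.n_clusters == int(np.ceil(7 / 3))


def test_cluster_size_must_be_positive(tiny_table):
    m = LinearModel(variables=["a"], coefficients=[1.0])
    r = rank(tiny_table, m)
    with pytest.raises(ValueError):
        cluster_distribution(r, 0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_cluster_counts_conserve_positives(seed):
    rng = np.random.default_rng(seed)
    r = random_ranking(rng, n_max=40, require_positive=False)
    size = int(rng.integers(1, r.n_total + 1))
    d = cluster_distribution(r, size)
    assert int(d.counts.sum()) == r.n_positive
    assert cluster_counts_oracle(r.labels.tolist(), size) == d.counts.tolist()


# ---------------------------------------------------------------- asymmetry
def _dist(percentages):
    p = np.asarray(percentages, dtype=float)
    return ClusterDistribution(
        cluster_size=10,
        counts=(p / 10).astype(int),
        sizes=np.full(len(p), 10),
        percentages=p,
    )


@pytest.mark.parametrize(
    "profile", [[10, 15, 20], [0, 10, 20, 30], [5, 5, 5], [0, 0, 0]]
)
def test_asymmetry_zero_for_mean_symmetric_or_flat(profile):
    """Profiles symmetric about their mean (zero third moment) and flat
    profiles (zero variance, degenerate) both give AI = 0."""
    assert asymmetry_index(_dist(profile)) == pytest.approx(0.0, abs=1e-12)


def test_asymmetry_matches_population_skewness():
    for profile in ([60, 10, 0, 0], [1, 2, 3, 10], [50, 25, 12, 6, 3]):
        expected = sps.skew(np.asarray(profile, float), bias=True)
        assert asymmetry_index(_dist(profile)) == pytest.approx(
            expected, abs=1e-12
        )


def test_asymmetry_needs_two_clusters():
    with pytest.raises(ValueError):
        asymmetry_index(_dist([100.0]))


def test_asymmetry_scale_invariance_counts_vs_percentages():
    # equal cluster sizes: skewness of counts equals skewness of percentages
    counts = np.array([9, 3, 1, 0, 2], float)
    d_counts = _dist(counts)
    d_pct = _dist(counts * 10.0)
    assert asymmetry_index(d_counts) == pytest.approx(asymmetry_index(d_pct))


# ------------------------------------------------------------------- quality
def test_quality_all_positives_up_front():
    labels = [1] * 5 + [0] * 20
    r = rank_scores([str(i) for i in range(25)], -np.arange(25.0), labels)
    d = cluster_distribution(r, 5)
    q = quality(d)
    assert q > 0
    assert q == pytest.approx(asymmetry_index(d) * 100.0)


def test_quality_zero_for_uniform_positives():
    labels = [1, 0, 0, 0, 0] * 4
    r = rank_scores([str(i) for i in range(20)], -np.arange(20.0), labels)
    assert quality(cluster_distribution(r, 5)) == 0.0


def test_quality_invariant_under_score_doubling(small_planted):
    table, _ = small_planted
    m = LinearModel(variables=["d00", "d01"], coefficients=[1.0, 0.5])
    m2 = LinearModel(variables=["d00", "d01"], coefficients=[2.0, 1.0])
    q1 = quality(cluster_distribution(rank(table, m), 30))
    q2 = quality(cluster_distribution(rank(table, m2), 30))
    assert q1 == q2


# ----------------------------------------------------------------- confusion
def test_confusion_forced_arithmetic_unbalanced():
    # 977 instances, 138 positives, prefix cut at 138 with 48 hits
    labels = np.zeros(977, dtype=int)
    labels[:48] = 1  # 48 positives inside the prefix
    labels[138 : 138 + 90] = 1  # remaining 90 positives outside
    r = rank_scores([str(i) for i in range(977)], -np.arange(977.0), labels)
    cm = confusion_from_ranking(r, 138)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (48, 90, 90, 749)


def test_confusion_perfect_ranking_prefix_P():
    labels = [1] * 4 + [0] * 8
    r = rank_scores([str(i) for i in range(12)], -np.arange(12.0), labels)
    cm = confusion_from_ranking(r, 4)
    assert cm.fp == cm.fn == 0


def test_confusion_out_of_range():
    r = rank_scores(["a", "b"], [1.0, 0.0], [1, 0])
    with pytest.raises(ValueError):
        confusion_from_ranking(r, 3)


def test_confusion_invariants_on_random_rankings():
    rng = np.random.default_rng(77)
    for _ in range(100):
        r = random_ranking(rng, n_max=40)
        n_pred = int(rng.integers(0, r.n_total + 1))
        cm = confusion_from_ranking(r, n_pred)
        assert cm.n_total == r.n_total
        assert cm.n_positive == r.n_positive
        assert cm.n_predicted_positive == n_pred
        # cross-check against sklearn's confusion matrix
        y_true = r.labels
        y_pred = np.zeros(r.n_total, dtype=int)
        y_pred[:n_pred] = 1
        sk = sk_confusion(y_true, y_pred, labels=[0, 1])
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == tuple(sk.ravel())


# ------------------------------------------------------------------- metrics
def test_metrics_degenerate_flagged():
    m = classification_metrics(ConfusionMatrix(tp=0, fp=2, fn=0, tn=5))
    assert m.sensitivity == 0.0
    assert "sensitivity" in m.degenerate


def test_metrics_perfect_matrix():
    m = classification_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=10))
    assert m.mcc == pytest.approx(1.0)
    assert m.precision == m.accuracy == m.sensitivity == m.specificity == 1.0


def test_mcc_against_sklearn():
    cases = [(48, 90, 90, 749), (3, 1, 2, 10), (1, 0, 5, 3)]
    for tp, fp, fn, tn in cases:
        m = classification_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        assert m.mcc == pytest.approx(sk_mcc(y_true, y_pred), abs=1e-12)


# ----------------------------------------------- exhaustive small-N equality
def test_all_statistics_match_oracles_on_exhaustive_small_rankings():
    """Every statistic equals its brute-force oracle on all rankings, N <= 8."""
    for n in range(2, 9):
        for r in all_rankings(n):
            labels = r.labels.tolist()
            P = sum(labels)
            if P:
                for f in (0.05, 0.25, 0.5, 1.0):
                    assert enrichment_factor(r, f) == pytest.approx(
                        ef_oracle(labels, f), abs=1e-12
                    )
            for size in range(1, n + 1):
                d = cluster_distribution(r, size)
                assert d.counts.tolist() == cluster_counts_oracle(labels, size)
                if d.n_clusters >= 2:
                    expected = sps.skew(d.percentages, bias=True)
                    got = asymmetry_index(d)
                    if np.isnan(expected):  # zero variance: degenerate -> 0
                        assert got == 0.0
                    else:
                        assert got == pytest.approx(expected, abs=1e-10)
            for n_pred in range(0, n + 1):
                cm = confusion_from_ranking(r, n_pred)
                assert cm.tp == sum(labels[:n_pred])
                assert cm.n_total == n and cm.n_positive == P


def test_evaluate_ranking_bundles_consistently():
    labels = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
    r = rank_scores([str(i) for i in range(10)], -np.arange(10.0), labels)
    rep = evaluate_ranking(r)  # defaults: prefix cut and cluster at P=3
    assert rep.confusion.n_predicted_positive == 3
    assert 0 <= rep.precision <= 1 and -1 <= rep.mcc <= 1
    assert rep.top_cluster_positive_fraction == pytest.approx(2 / 3)
    assert "MCC" in rep.to_text()
    assert rep.to_dict()["confusion"]["tp"] == rep.confusion.tp
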