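import numpy as np
import pytest
from scipy import stats

from campaignimpact.errors import EmptyInputError, NonEstimableError
from campaignimpact.reach import (build_retweet_network, compare_engagement,
                                  detect_communities, mann_whitney,
                                  reach_summary, welch_t)
from campaignimpact.synthetic import (GeneratorConfig, generate_corpus,
                                      generate_retweet_graph,
                                      retweet_posts_from_edges, _communities)

from conftest import make_post


# --------------------------------------------------------------------------
# Welch t

def test_welch_identical_samples():
    t, df, p = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_closed_form():
    a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
    t, df, p = welch_t(a, b)
    sa2 = np.var(a, ddof=1) / len(a)
    sb2 = np.var(b, ddof=1) / len(b)
    assert t == pytest.approx((np.mean(a) - np.mean(b)) / np.sqrt(sa2 + sb2), abs=1e-10)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_welch_antisymmetry():
    a, b = [1.0, 4.0, 2.0], [5.0, 3.0, 8.0]
    t1, _, p1 = welch_t(a, b)
    t2, _, p2 = welch_t(b, a)
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


def test_welch_degenerate_rejected():
    with pytest.raises(NonEstimableError):
        welch_t([2, 2, 2], [2, 2, 2])
    with pytest.raises(EmptyInputError):
        welch_t([1], [1, 2])


# --------------------------------------------------------------------------
# Mann-Whitney U

def test_mann_whitney_pair_identity():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(0, 10, size=rng.integers(2, 12)).astype(float)
        b = rng.integers(0, 10, size=rng.integers(2, 12)).astype(float)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))


def test_mann_whitney_enumerated():
    u, _ = mann_whitney([1, 2], [3, 4])  # no pair where a > b
    assert u == 0.0


def test_mann_whitney_identical_multisets():
    a = [3.0, 1.0, 2.0]
    u, p = mann_whitney(a, list(a))
    assert u == pytest.approx(len(a) ** 2 / 2)


def test_two_sample_stats_match_reference_on_random_fixtures():
    """Both statistics agree with independent implementations to 1e-8."""
    rng = np.random.default_rng(42)
    for i in range(100):
        na, nb = rng.integers(5, 40, size=2)
        a = np.round(rng.gamma(2.0, 3.0, size=na), 1)  # ties likely
        b = np.round(rng.gamma(2.0, 4.0, size=nb), 1)
        if np.var(a) == 0 and np.var(b) == 0:
            continue
        t, df, p = welch_t(a, b)
        ref_t = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref_t.statistic, abs=1e-8)
        assert p == pytest.approx(ref_t.pvalue, abs=1e-8)
        u, pu = mann_whitney(a, b)
        ref_u = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        assert u == pytest.approx(ref_u.statistic, abs=1e-8)
        assert pu == pytest.approx(ref_u.pvalue, abs=1e-8)


# --------------------------------------------------------------------------
# Retweet network

def test_retweet_edges_aggregate_counts():
    posts = [make_post("rt x", user_id="A", is_retweet=True,
                       retweeted_user_id="B", post_id=f"p{i}",
                       ts=f"2020-02-2{i}T10:00:00") for i in range(3)]
    g = build_retweet_network(posts)
    assert list(g.edges(data="weight")) == [("A", "B", 3)]


def test_no_retweets_empty_network():
    g = build_retweet_network([make_post("plain post")])
    assert g.number_of_nodes() == 0


def test_missing_source_skipped(caplog):
    posts = [make_post("rt x", is_retweet=True, retweeted_user_id=None)]
    with caplog.at_level("WARNING"):
        g = build_retweet_network(posts)
    assert g.number_of_edges() == 0 and "no source" in caplog.text


def test_network_matches_generator_edges():
    cfg = GeneratorConfig(n_target_users=15, n_baseline_users=25,
                          n_communities=2, seed=13)
    edges = generate_retweet_graph(cfg)
    g = build_retweet_network(retweet_posts_from_edges(edges))
    assert {(u, v, d["weight"]) for u, v, d in g.edges(data=True)} == set(edges)


# --------------------------------------------------------------------------
# Communities

def _graph_from_edges(pairs):
    import networkx as nx
    g = nx.DiGraph()
    for u, v in pairs:
        g.add_edge(u, v, weight=1)
    return g


def test_two_disjoint_triangles():
    g = _graph_from_edges([("a", "b"), ("b", "c"), ("c", "a"),
                           ("x", "y"), ("y", "z"), ("z", "x")])
    part = detect_communities(g)
    assert sorted(map(sorted, part.communities)) == [["a", "b", "c"], ["x", "y", "z"]]


def test_complete_graph_single_community():
    import itertools
    g = _graph_from_edges(itertools.combinations("abcde", 2))
    part = detect_communities(g)
    assert len(part.communities) == 1


def test_single_node_graph():
    import networkx as nx
    g = nx.DiGraph()
    g.add_node("solo")
    part = detect_communities(g)
    assert part.communities == [frozenset({"solo"})]


def test_partition_covers_nodes_exactly_once():
    cfg = GeneratorConfig(n_target_users=30, n_baseline_users=50,
                          n_communities=3, seed=5)
    g = build_retweet_network(retweet_posts_from_edges(generate_retweet_graph(cfg)))
    part = detect_communities(g)
    assert sorted(u for c in part.communities for u in c) == sorted(g.nodes())


def test_planted_partition_recovered():
    """Walktrap recovers 4 planted blocks of 25 nodes (ARI >= 0.9)."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    cfg = GeneratorConfig(n_target_users=40, n_baseline_users=60,
                          n_communities=4, intra_edge_prob=0.3,
                          inter_edge_prob=0.005, seed=11)
    g = build_retweet_network(retweet_posts_from_edges(generate_retweet_graph(cfg)))
    part = detect_communities(g)
    truth = _communities(cfg)
    nodes = sorted(g.nodes())
    ari = sklearn_metrics.adjusted_rand_score(
        [truth[u] for u in nodes], [part.membership[u] for u in nodes])
    assert ari >= 0.9


# --------------------------------------------------------------------------
# Reach summary

def test_reach_summary_small_fixture():
    posts = [
        make_post("join us", user_id="camp", follower_count=100,
                  retweet_count=7, like_count=9, post_id="c1"),
        make_post("rt join us", user_id="r1", follower_count=10,
                  is_retweet=True, retweeted_user_id="camp", post_id="r1p"),
        make_post("rt join us", user_id="r2", follower_count=20,
                  is_retweet=True, retweeted_user_id="camp", post_id="r2p"),
        make_post("rt join us", user_id="r3", follower_count=30,
                  is_retweet=True, retweeted_user_id="camp", post_id="r3p"),
    ]
    s = reach_summary(posts, ["camp"])
    assert s.total_followers == 160
    assert s.mean_retweets == 7 and s.mean_likes == 9
    assert s.median_followers_of_retweeters == 20
    assert s.n_retweeters == 3
    assert s.top_accounts[0][2] == 30


def test_reach_summary_matches_generator_truth():
    cfg = GeneratorConfig(n_target_users=20, n_baseline_users=30, seed=17)
    posts, truth = generate_corpus(cfg)
    s = reach_summary(posts, [truth.campaign_account])
    rts = np.array(truth.campaign_retweet_counts, dtype=float)
    assert s.n_campaign_posts == cfg.n_campaign_posts
    assert s.mean_retweets == pytest.approx(rts.mean())
    assert s.median_retweets == pytest.approx(np.median(rts))
    # every target user retweets the campaign account exactly once
    assert s.n_retweeters == cfg.n_target_users
    expected = sum(u.follower_count for u in truth.users.values()) + 50000
    assert s.total_followers == expected


def test_compare_engagement_bundle():
    rng = np.random.default_rng(1)
    a = rng.poisson(50, 200).astype(float)
    b = rng.poisson(40, 200).astype(float)
    out = compare_engagement(a, b)
    assert out["welch_p"] < 0.001 and out["mann_whitney_p"] < 0.001
    assert out["welch_t"] > 0
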