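"""Campaign reach: audience bounds, engagement statistics, retweet network.

The follower sum over participating accounts is a *hypothetical maximum*
audience (follower overlap between accounts cannot be deduplicated).  The
retweet network is a directed weighted graph retweeter -> author with one edge
per observed pair; community detection runs on its symmetrized form using the
Walktrap short-random-walk algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

from .corpus import Post
from .errors import EmptyInputError, NonEstimableError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Two-sample statistics (direct formula implementations; scipy supplies only
# the reference distributions for p-values).

def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, degrees of freedom, two-sided p).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch-Satterthwaite approximation to the degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EmptyInputError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise NonEstimableError("both samples have zero variance")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with normal-approximation p-value.

    Returns (U_a, two-sided p); the variance is tie-corrected and a 0.5
    continuity correction is applied.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("samples must be nonempty")
    na, nb = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # midranks
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    n = na + nb
    mean_u = na * nb / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0.0:
        return u_a, 1.0  # all values identical: no evidence either way
    z = (abs(u_a - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return u_a, float(min(p, 1.0))


# --------------------------------------------------------------------------
# Retweet network and communities.

def build_retweet_network(posts: Iterable[Post]) -> nx.DiGraph:
    """Directed weighted graph retweeter -> original author.

    One edge per (retweeter, author) pair, weight = number of retweets
    observed.  Self-retweets and retweets with a missing source are skipped
    (the latter with a logged warning).  Users who neither retweet nor get
    retweeted do not appear.
    """
    g = nx.DiGraph()
    for post in posts:
        if not post.is_retweet:
            continue
        if post.retweeted_user_id is None:
            logger.warning("retweet %s has no source user; skipped", post.post_id)
            continue
        if post.retweeted_user_id == post.user_id:
            continue
        u, v = post.user_id, post.retweeted_user_id
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g


@dataclass(frozen=True)
class CommunityPartition:
    """Node partition from community detection."""

    membership: dict[str, int]
    communities: list[frozenset[str]] = field(repr=False)  # sorted by size desc
    modularity: float

    def top(self, k: int = 5) -> list[frozenset[str]]:
        """The k largest communities by node count."""
        return self.communities[:k]


def detect_communities(network: nx.DiGraph | nx.Graph, walk_length: int = 4) -> CommunityPartition:
    """Walktrap community detection on the weight-aggregated undirected graph.

    Random-walk distances over ``walk_length`` steps drive an agglomerative
    merge; the dendrogram is cut at maximum modularity.  Deterministic for a
    given graph.
    """
    nodes = sorted(network.nodes())
    if not nodes:
        raise EmptyInputError("network has no nodes")
    index = {u: i for i, u in enumerate(nodes)}
    # Symmetrize: sum weights in both directions.
    agg: dict[tuple[int, int], float] = {}
    for u, v, data in network.edges(data=True):
        i, j = index[u], index[v]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        agg[key] = agg.get(key, 0.0) + float(data.get("weight", 1.0))
    g = ig.Graph(n=len(nodes), edges=list(agg.keys()))
    g.es["weight"] = list(agg.values())
    if g.ecount() == 0:
        membership = {u: i for i, u in enumerate(nodes)}
        comms = [frozenset([u]) for u in nodes]
        return CommunityPartition(membership=membership, communities=comms, modularity=0.0)
    dendro = g.community_walktrap(weights="weight", steps=walk_length)
    clustering = dendro.as_clustering()
    raw = clustering.membership
    groups: dict[int, set[str]] = {}
    for u, i in index.items():
        groups.setdefault(raw[i], set()).add(u)
    ordered = sorted(groups.values(), key=lambda s: (-len(s), min(s)))
    membership = {u: ci for ci, comm in enumerate(ordered) for u in comm}
    mod = g.modularity(raw, weights="weight")
    return CommunityPartition(membership=membership,
                              communities=[frozenset(c) for c in ordered],
                              modularity=float(mod))


# --------------------------------------------------------------------------
# Reach summary.

@dataclass(frozen=True)
class ReachSummary:
    """Audience and engagement summary for one campaign's corpus."""

    total_followers: int            # hypothetical maximum audience
    n_participants: int
    mean_retweets: float
    median_retweets: float
    mean_likes: float
    median_likes: float
    mean_followers_of_retweeters: float
    median_followers_of_retweeters: float
    n_campaign_posts: int
    n_retweeters: int
    top_accounts: list[tuple[str, str, int]]  # (user_id, display_name, followers)


def reach_summary(posts: Sequence[Post], campaign_account_ids: Iterable[str],
                  top_k: int = 20) -> ReachSummary:
    """Summarise reach of campaign-originating content.

    Campaign content = original (non-retweet) posts authored by the campaign
    accounts; engagement = their retweet/like counts; the retweeter pool =
    accounts that retweeted a campaign account.  Follower sums count each
    participating account once, at its maximum observed follower count.
    """
    campaign_ids = set(campaign_account_ids)
    followers: dict[str, int] = {}
    names: dict[str, str] = {}
    campaign_posts = []
    retweeters: set[str] = set()
    for post in posts:
        followers[post.user_id] = max(followers.get(post.user_id, 0), post.follower_count)
        names.setdefault(post.user_id, post.display_name)
        if (not post.is_retweet) and post.user_id in campaign_ids:
            campaign_posts.append(post)
        if post.is_retweet and post.retweeted_user_id in campaign_ids:
            retweeters.add(post.user_id)
    rts = np.array([p.retweet_count for p in campaign_posts], dtype=float)
    likes = np.array([p.like_count for p in campaign_posts], dtype=float)
    rt_follow = np.array([followers[u] for u in retweeters], dtype=float)
    ranked = sorted(((u, names[u], followers[u]) for u in retweeters),
                    key=lambda t: (-t[2], t[0]))
    return ReachSummary(
        total_followers=int(sum(followers.values())),
        n_participants=len(followers),
        mean_retweets=float(rts.mean()) if len(rts) else float("nan"),
        median_retweets=float(np.median(rts)) if len(rts) else float("nan"),
        mean_likes=float(likes.mean()) if len(likes) else float("nan"),
        median_likes=float(np.median(likes)) if len(likes) else float("nan"),
        mean_followers_of_retweeters=float(rt_follow.mean()) if len(rt_follow) else float("nan"),
        median_followers_of_retweeters=float(np.median(rt_follow)) if len(rt_follow) else float("nan"),
        n_campaign_posts=len(campaign_posts),
        n_retweeters=len(retweeters),
        top_accounts=ranked[:top_k],
    )


def compare_engagement(counts_a: Sequence[float], counts_b: Sequence[float]) -> dict:
    """Welch t and Mann-Whitney U comparison of two engagement-count samples
    (e.g. per-post retweet counts of two campaigns)."""
    t, df, p_t = welch_t(counts_a, counts_b)
    u, p_u = mann_whitney(counts_a, counts_b)
    return {"welch_t": t, "welch_df": df, "welch_p": p_t,
            "mann_whitney_u": u, "mann_whitney_p": p_u}
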