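"""Vocabulary contrasts between groups and keyword-prevalence change tests.

For a lexical category of interest, the tweets containing at least one of its
words are split by group (typically female vs male authors) and each word is
scored with a smoothed odds ratio of per-tweet usage: OR > 1 marks words
leaning toward group 1, OR < 1 toward group 2.  A two-proportion z-test
tracks how the share of posts matching a keyword set (e.g. covid*,
coronavirus) changes across a split date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from scipy import stats

from .corpus import Post
from .errors import ConfigurationError, EmptyInputError
from ._resources import default_stopwords
from .lexicon import Lexicon, tokenize

logger = logging.getLogger(__name__)


def category_tweet_filter(posts: Iterable[Post], lexicon: Lexicon, category: str) -> list[Post]:
    """Posts whose tokens match at least one entry of the category."""
    if category not in lexicon.categories:
        raise ConfigurationError(f"unknown category {category!r}")
    return [p for p in posts
            if any(category in lexicon.match(t) for t in tokenize(p.text))]


@dataclass(frozen=True)
class OddsRatioEntry:
    """A word's per-tweet usage counts in two groups and its smoothed OR."""

    word: str
    a: int  # group-1 tweets containing the word
    b: int  # group-1 tweets not containing it
    c: int  # group-2 tweets containing it
    d: int  # group-2 tweets not containing it
    odds_ratio: float

    @staticmethod
    def smoothed_or(a: int, b: int, c: int, d: int) -> float:
        """Haldane-Anscombe 1/2-smoothed odds ratio; finite and positive even
        with zero cells."""
        return ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))


def _word_counts(posts: Sequence[Post], count_unit: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for post in posts:
        toks = tokenize(post.text)
        for word in (set(toks) if count_unit == "tweet" else toks):
            counts[word] = counts.get(word, 0) + 1
    return counts


def odds_ratio_ranking(
    posts_g1: Sequence[Post],
    posts_g2: Sequence[Post],
    top_k: int = 30,
    stopwords: frozenset[str] | None = None,
    min_total: int = 1,
    count_unit: str = "tweet",
) -> tuple[list[OddsRatioEntry], list[OddsRatioEntry]]:
    """(group-1-leaning, group-2-leaning) ranked word lists.

    With the default ``count_unit="tweet"`` a word counts once per tweet it
    appears in ("used by" a tweet is a binary notion); ``count_unit="token"``
    switches to raw occurrence counts.  The first list is the top_k words by
    descending smoothed OR, the second by ascending OR; ties break by total
    frequency (descending) then lexicographically.  A small stopword list is
    excluded by default; pass ``stopwords=frozenset()`` to disable.
    """
    if not posts_g1 or not posts_g2:
        raise EmptyInputError("both groups need at least one post")
    if count_unit not in ("tweet", "token"):
        raise ConfigurationError(f"count_unit must be 'tweet' or 'token', got {count_unit!r}")
    if stopwords is None:
        stopwords = default_stopwords()
    c1 = _word_counts(posts_g1, count_unit)
    c2 = _word_counts(posts_g2, count_unit)
    if count_unit == "tweet":
        n1, n2 = len(posts_g1), len(posts_g2)
    else:
        n1, n2 = sum(c1.values()), sum(c2.values())
    vocab = (set(c1) | set(c2)) - set(stopwords)
    vocab = {w for w in vocab if c1.get(w, 0) + c2.get(w, 0) >= min_total}
    if not vocab:
        logger.warning("empty vocabulary after filtering; returning empty lists")
        return [], []
    entries = []
    for word in vocab:
        a, c = c1.get(word, 0), c2.get(word, 0)
        entries.append(OddsRatioEntry(
            word=word, a=a, b=n1 - a, c=c, d=n2 - c,
            odds_ratio=OddsRatioEntry.smoothed_or(a, n1 - a, c, n2 - c),
        ))
    g1_lead = sorted(entries, key=lambda e: (-e.odds_ratio, -(e.a + e.c), e.word))
    g2_lead = sorted(entries, key=lambda e: (e.odds_ratio, -(e.a + e.c), e.word))
    return g1_lead[:top_k], g2_lead[:top_k]


@dataclass(frozen=True)
class PrevalenceTest:
    """Change in the share of posts matching a keyword set across a split date."""

    keywords: tuple[str, ...]
    p_pre: float
    p_post: float
    n_pre: int
    n_post: int
    z: float
    p_value: float


def _keyword_matcher(keywords: Iterable[str]):
    literals, prefixes = set(), []
    for kw in keywords:
        kw = kw.strip().lower().lstrip("#@")
        if not kw:
            continue
        if kw.endswith("*"):
            prefixes.append(kw[:-1])
        else:
            literals.add(kw)
    prefixes = tuple(prefixes)

    def matches(post: Post) -> bool:
        for tok in tokenize(post.text):
            if tok in literals or any(tok.startswith(p) for p in prefixes):
                return True
        return False

    return matches


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z statistic and two-sided p-value for
    the change from proportion k1/n1 to k2/n2."""
    if n1 == 0 or n2 == 0:
        raise EmptyInputError("both periods must contain posts")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = (pooled * (1 - pooled) * (1 / n1 + 1 / n2)) ** 0.5
    if denom == 0.0:
        return 0.0, 1.0
    z = (p2 - p1) / denom
    return z, float(2.0 * stats.norm.sf(abs(z)))


def prevalence_z_test(posts: Sequence[Post], keyword_set: Iterable[str],
                      split_day: date) -> PrevalenceTest:
    """Two-proportion z-test of keyword prevalence before vs from ``split_day``.

    Keywords support trailing-wildcard prefixes (``covid*``); matching is on
    whole tokens after the standard tokenization.
    """
    keywords = tuple(keyword_set)
    matches = _keyword_matcher(keywords)
    k1 = n1 = k2 = n2 = 0
    for post in posts:
        if post.date < split_day:
            n1 += 1
            k1 += matches(post)
        else:
            n2 += 1
            k2 += matches(post)
    if n1 == 0 or n2 == 0:
        raise EmptyInputError("both periods must contain at least one post")
    z, p = two_proportion_z(k1, n1, k2, n2)
    return PrevalenceTest(keywords=keywords, p_pre=k1 / n1, p_post=k2 / n2,
                          n_pre=n1, n_post=n2, z=z, p_value=p)
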