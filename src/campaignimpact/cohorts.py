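"""Cohort assembly: campaign engagement detection, day-0 anchoring, windows.

Target users are anchored at the date of their first campaign-matching post
("day 0"); control users, who posted on general diet/health terms but never on
campaign terms, all share the campaign's start date as day 0.  Eligibility
requires at least ``min_posts`` posts in each of the before and after windows.
Day boundaries are calendar days in UTC; the pre-window is ``[day0-B, day0)``
and the post-window ``[day0, day0+A)``, both half-open, with day 0 assigned to
the post period because the engagement marks the start of exposure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Post
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

TARGET = "target"
BASELINE = "baseline"


def normalize_terms(terms: Iterable[str]) -> frozenset[str]:
    """Lowercase keyword set with leading '#'/'@' stripped."""
    out = set()
    for term in terms:
        term = term.strip().lower().lstrip("#@")
        if term:
            out.add(term)
    return frozenset(out)


_MATCH_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MATCH_TOKEN_RE = re.compile(r"[\w']+")


def _match_tokens(text: str) -> list[str]:
    """Tokens for keyword matching: unlike language scoring, @-mention bodies
    are kept, because retweeting/addressing a campaign account ("@NEDA") is an
    engagement with it."""
    return _MATCH_TOKEN_RE.findall(_MATCH_URL_RE.sub(" ", text.lower()))


def post_matches(post: Post, terms: frozenset[str]) -> bool:
    """Whole-token, case-insensitive match (substring matching is rejected so
    a campaign acronym cannot fire inside an unrelated word)."""
    return any(tok in terms for tok in _match_tokens(post.text))


def detect_day0(posts_of_user: Sequence[Post], campaign_terms: Iterable[str]) -> date | None:
    """Date of the chronologically first campaign-matching post, else None."""
    terms = normalize_terms(campaign_terms)
    if not terms:
        raise ConfigurationError("campaign term set is empty")
    best: Post | None = None
    for post in posts_of_user:
        if post_matches(post, terms):
            if best is None or post.timestamp < best.timestamp:
                best = post
    return None if best is None else best.date


def first_matching_post(posts_of_user: Sequence[Post], terms: frozenset[str]) -> Post | None:
    best = None
    for post in posts_of_user:
        if post_matches(post, terms):
            if best is None or post.timestamp < best.timestamp:
                best = post
    return best


def partition_window(
    posts_of_user: Sequence[Post],
    day0: date,
    days_before: int = 15,
    days_after: int = 15,
    campaign_terms: Iterable[str] | None = None,
    include_day0_post: bool = False,
) -> tuple[list[Post], list[Post]]:
    """(pre_posts, post_posts) around day 0; posts outside both windows dropped.

    When ``campaign_terms`` is given and ``include_day0_post`` is False, the
    first campaign-matching post (the engagement itself) is excluded from the
    post window so the retweeted campaign text cannot mechanically inflate the
    measured language change.
    """
    if days_before < 0 or days_after < 0:
        raise ConfigurationError("window lengths must be nonnegative")
    skip_id = None
    if campaign_terms is not None and not include_day0_post:
        first = first_matching_post(posts_of_user, normalize_terms(campaign_terms))
        if first is not None:
            skip_id = first.post_id
    pre, post_ = [], []
    for post in posts_of_user:
        offset = (post.date - day0).days
        if -days_before <= offset < 0:
            pre.append(post)
        elif 0 <= offset < days_after and post.post_id != skip_id:
            post_.append(post)
    return pre, post_


@dataclass(frozen=True)
class CohortAssignment:
    """A user's role, anchor date, and window eligibility."""

    user_id: str
    role: str           # target | baseline
    day0: date
    eligible: bool
    n_pre: int
    n_post: int

    def __post_init__(self) -> None:
        if self.role not in (TARGET, BASELINE):
            raise ValueError(f"bad role {self.role!r}")


def build_cohorts(
    posts: Iterable[Post],
    campaign_terms: Iterable[str],
    baseline_terms: Iterable[str],
    campaign_start: date,
    min_posts: int = 3,
    days_before: int = 15,
    days_after: int = 15,
    include_day0_post: bool = False,
) -> list[CohortAssignment]:
    """Assign every matching user to exactly one cohort.

    Any user with a campaign-term match is a target (anchored at their own
    day 0) and never a control; users matching only the diet/health baseline
    terms are controls anchored at ``campaign_start``; users matching neither
    are excluded.  ``n_pre``/``n_post`` count the posts retained in each
    window (so the excluded day-0 campaign post does not count toward its
    author's activity), and ``eligible`` is the >= min_posts rule on both.
    """
    if not isinstance(campaign_start, date):
        raise ConfigurationError(f"campaign_start must be a date, got {campaign_start!r}")
    c_terms = normalize_terms(campaign_terms)
    b_terms = normalize_terms(baseline_terms)
    if not c_terms:
        raise ConfigurationError("campaign term set is empty")

    by_user: dict[str, list[Post]] = {}
    for post in posts:
        by_user.setdefault(post.user_id, []).append(post)

    assignments = []
    for uid in sorted(by_user):
        user_posts = sorted(by_user[uid], key=lambda p: (p.timestamp, p.post_id))
        day0 = detect_day0(user_posts, c_terms)
        if day0 is not None:
            role = TARGET
            pre, post_ = partition_window(user_posts, day0, days_before, days_after,
                                          campaign_terms=c_terms,
                                          include_day0_post=include_day0_post)
        elif any(post_matches(p, b_terms) for p in user_posts):
            role, day0 = BASELINE, campaign_start
            pre, post_ = partition_window(user_posts, day0, days_before, days_after)
        else:
            continue
        n_pre, n_post = len(pre), len(post_)
        assignments.append(CohortAssignment(
            user_id=uid, role=role, day0=day0,
            eligible=(n_pre >= min_posts and n_post >= min_posts),
            n_pre=n_pre, n_post=n_post,
        ))
    return assignments


def assignments_to_frame(assignments: Sequence[CohortAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.user_id, a.role, a.day0.isoformat(), a.eligible, a.n_pre, a.n_post)
         for a in assignments],
        columns=["user_id", "role", "day0", "eligible", "n_pre", "n_post"],
    )
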