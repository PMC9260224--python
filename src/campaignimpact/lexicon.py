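"""Lexicon-based scoring of text into category rate series.

The dictionary format is the tab-separated ``.dic`` dialect: a header block of
``id<TAB>name`` lines delimited by ``%`` lines, followed by ``word<TAB>id...``
entries where a trailing ``*`` marks a prefix pattern.  A category *rate* for a
user-day is the fraction of that day's tokens matching any of the category's
entries; a token may count toward several categories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Post
from .errors import ConfigurationError

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[^\W\s]+(?:'[^\W\s]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: URLs and @-mentions removed, ``#`` stripped from
    hashtags (body kept), split on non-word characters, internal apostrophes kept."""
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    toks = _TOKEN_RE.findall(text.lower())
    return [t.strip("'_") for t in toks if t.strip("'_")]


class Lexicon:
    """Category dictionary with literal and trailing-wildcard prefix entries."""

    def __init__(self, patterns: Mapping[str, Iterable[str]]):
        self.categories: list[str] = list(patterns)
        if len(set(self.categories)) != len(self.categories):
            raise ConfigurationError("duplicate category names in lexicon")
        self.literals: dict[str, set[str]] = {}
        self.prefixes: dict[str, tuple[str, ...]] = {}
        for cat, entries in patterns.items():
            lits, prefs = set(), []
            for entry in entries:
                entry = entry.strip().lower()
                if not entry or entry == "*":
                    raise ConfigurationError(f"empty pattern in category {cat!r}")
                if entry.endswith("*"):
                    prefs.append(entry[:-1])
                else:
                    lits.add(entry)
            self.literals[cat] = lits
            self.prefixes[cat] = tuple(sorted(prefs))
        self._cache: dict[str, tuple[str, ...]] = {}

    @classmethod
    def from_dic(cls, path: str | Path) -> "Lexicon":
        """Parse a ``.dic`` file (header of id/name pairs between % lines)."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        it = iter(lines)
        id_to_name: dict[str, str] = {}
        in_header = False
        patterns: dict[str, list[str]] = {}
        for line in it:
            line = line.strip()
            if not line:
                continue
            if line == "%":
                if not in_header and not id_to_name:
                    in_header = True
                    continue
                in_header = False
                continue
            parts = line.split("\t")
            if in_header:
                if len(parts) < 2:
                    raise ConfigurationError(f"bad header line in .dic: {line!r}")
                id_to_name[parts[0].strip()] = parts[1].strip()
                patterns[parts[1].strip()] = []
            else:
                if len(parts) < 2:
                    raise ConfigurationError(f"bad entry line in .dic: {line!r}")
                word = parts[0].strip().lower()
                for cid in parts[1:]:
                    cid = cid.strip()
                    if not cid:
                        continue
                    if cid not in id_to_name:
                        raise ConfigurationError(f"unknown category id {cid!r} for {word!r}")
                    patterns[id_to_name[cid]].append(word)
        if not patterns:
            raise ConfigurationError(f"no categories parsed from {path}")
        return cls(patterns)

    def match(self, token: str) -> tuple[str, ...]:
        """Categories the token belongs to (literal exact or prefix match); cached."""
        hit = self._cache.get(token)
        if hit is None:
            hit = tuple(
                cat for cat in self.categories
                if token in self.literals[cat]
                or any(token.startswith(p) for p in self.prefixes[cat])
            )
            self._cache[token] = hit
        return hit

    def matches_category(self, token: str, category: str) -> bool:
        if category not in self.literals:
            raise ConfigurationError(f"unknown category {category!r}")
        return category in self.match(token)


def score_day(tokens: Sequence[str], lexicon: Lexicon) -> dict[str, float] | None:
    """Per-category rate vector for one user-day, or None when there are no
    tokens (a silent day is missing data, not a zero rate)."""
    n = len(tokens)
    if n == 0:
        return None
    counts = dict.fromkeys(lexicon.categories, 0)
    for tok in tokens:
        for cat in lexicon.match(tok):
            counts[cat] += 1
    return {cat: counts[cat] / n for cat in lexicon.categories}


@dataclass(frozen=True)
class DayVector:
    """Category rates for all of one user's tokens on one relative day."""

    user_id: str
    relative_day: int
    token_count: int
    category_rates: dict[str, float]


def compute_day_vectors(
    posts: Iterable[Post],
    day0_by_user: Mapping[str, date],
    lexicon: Lexicon,
    days_before: int = 15,
    days_after: int = 15,
    exclude_posts: set[str] | None = None,
    score_retweets: bool = True,
) -> list[DayVector]:
    """Aggregate every user's posts into per-day category rate vectors.

    Only posts of users present in ``day0_by_user`` and falling inside the
    [-days_before, days_after) relative window contribute.  ``exclude_posts``
    removes specific post ids (the day-0 campaign post) from scoring;
    ``score_retweets=False`` drops retweeted text from a user's own language.
    """
    token_counts: dict[tuple[str, int], int] = {}
    cat_counts: dict[tuple[str, int], dict[str, int]] = {}
    for post in posts:
        day0 = day0_by_user.get(post.user_id)
        if day0 is None:
            continue
        if exclude_posts and post.post_id in exclude_posts:
            continue
        if not score_retweets and post.is_retweet:
            continue
        rel = (post.date - day0).days
        if rel < -days_before or rel >= days_after:
            continue
        toks = tokenize(post.text)
        if not toks:
            continue
        key = (post.user_id, rel)
        token_counts[key] = token_counts.get(key, 0) + len(toks)
        cc = cat_counts.setdefault(key, dict.fromkeys(lexicon.categories, 0))
        for tok in toks:
            for cat in lexicon.match(tok):
                cc[cat] += 1
    vectors = []
    for (uid, rel), n_tok in token_counts.items():
        cc = cat_counts[(uid, rel)]
        vectors.append(DayVector(
            user_id=uid, relative_day=rel, token_count=n_tok,
            category_rates={cat: cc[cat] / n_tok for cat in lexicon.categories},
        ))
    vectors.sort(key=lambda v: (v.user_id, v.relative_day))
    return vectors


@dataclass(frozen=True)
class CategorySeries:
    """Mean daily rate of one category for one group, on relative days
    ``-days_before .. days_after-1``."""

    category: str
    group: str
    days_before: int
    days_after: int
    values: np.ndarray          # length days_before + days_after
    n_users: np.ndarray         # contributing users per day
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.imputed is None:
            object.__setattr__(self, "imputed", np.zeros(len(self.values), dtype=bool))
        if len(self.values) != self.days_before + self.days_after:
            raise ValueError("series length must equal days_before + days_after")

    @property
    def relative_days(self) -> np.ndarray:
        return np.arange(-self.days_before, self.days_after)

    @property
    def pre(self) -> np.ndarray:
        return self.values[: self.days_before]

    @property
    def post(self) -> np.ndarray:
        return self.values[self.days_before:]


def build_series(
    day_vectors: Sequence[DayVector],
    category: str,
    group: str,
    user_ids: set[str],
    days_before: int = 15,
    days_after: int = 15,
) -> CategorySeries:
    """Mean-over-users daily series for one category and one user group.

    Each contributing user is weighted equally (per-user rate, then group
    mean), so hyperactive accounts do not dominate.  Users with no posts on a
    day are skipped, not zero-filled; a day with zero contributors is linearly
    interpolated from its neighbours and flagged in ``imputed``.
    """
    length = days_before + days_after
    sums = np.zeros(length)
    counts = np.zeros(length, dtype=int)
    for vec in day_vectors:
        if vec.user_id not in user_ids:
            continue
        idx = vec.relative_day + days_before
        if 0 <= idx < length:
            sums[idx] += vec.category_rates[category]
            counts[idx] += 1
    values = np.divide(sums, counts, out=np.full(length, np.nan), where=counts > 0)
    imputed = counts == 0
    if imputed.any():
        if imputed.all():
            values = np.zeros(length)
        else:
            ok = ~imputed
            values = np.interp(np.arange(length), np.flatnonzero(ok), values[ok])
    return CategorySeries(category=category, group=group,
                          days_before=days_before, days_after=days_after,
                          values=values, n_users=counts, imputed=imputed)


def series_to_frame(series_list: Sequence[CategorySeries]) -> pd.DataFrame:
    """Long-format table (category, group, relative_day, value, n_users, imputed)."""
    rows = []
    for s in series_list:
        for day, val, n, imp in zip(s.relative_days, s.values, s.n_users, s.imputed):
            rows.append((s.category, s.group, int(day), float(val), int(n), bool(imp)))
    return pd.DataFrame(rows, columns=["category", "group", "relative_day",
                                       "value", "n_users", "imputed"])
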