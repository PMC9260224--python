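"""Synthetic post corpora with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a target cohort whose members each engage with campaign content once
(their "day 0", jittered across the campaign week), a control cohort posting
on general diet/health vocabulary over the same span, per-user-day Poisson
posting counts, bag-of-words texts whose per-token category probability is
``base_rate`` before day 0 and ``base_rate * (1 + lift)`` afterwards for
lifted categories in the target cohort only, display names drawn from
gendered name lists (plus deliberately ambiguous and unresolvable ones), and
a retweet graph with planted communities.  Token streams are bags of lexicon
and filler words — no natural-language realism is attempted, so passing tests
demonstrate statistical recovery, not robustness to real tweet text.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from ._resources import (default_lexicon_path, default_campaign_terms,
                         default_surnames)
from .corpus import Post
from .errors import ConfigurationError
from .gender import NameDictionary
from .lexicon import Lexicon

#: Neutral filler vocabulary; none of these words match any entry of the
#: bundled lexicon (enforced by the test suite).
FILLER_WORDS = (
    "the and for with this that have from they will just when what about "
    "there some more time really think know going today week year people "
    "because never always around after before again very much such other "
    "could would should right still even back over down only little world "
    "where while being through every another between these those someone "
    "nothing everything morning evening story start end part new old big "
    "small same different next last"
).split()

#: Baseline-cohort marker terms; chosen from the bundled diet/health list but
#: outside the lexicon so they do not perturb category rates.
BASELINE_MARKERS = ("gym", "workout", "fitness", "selfcare")

_DEFAULT_BASE_RATE = 0.04


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_target_users: int = 100
    n_baseline_users: int = 200
    days_before: int = 15
    days_after: int = 15
    posts_per_user_day: float = 2.0
    tokens_per_post: tuple[int, int] = (8, 20)
    category_base_rates: dict[str, float] = field(default_factory=dict)
    injected_lifts: dict[str, float] = field(default_factory=dict)
    gender_mix: tuple[float, float, float] = (0.43, 0.18, 0.39)
    n_communities: int = 4
    seed: int = 0
    campaign_start: date = date(2020, 2, 24)
    campaign_week_days: int = 7
    active_prob: float = 0.9
    ambiguous_name_frac: float = 0.05
    intra_edge_prob: float = 0.25
    inter_edge_prob: float = 0.005
    n_campaign_posts: int = 20
    campaign_account: str = "nedastaff"

    def __post_init__(self) -> None:
        if self.n_target_users < 1 or self.n_baseline_users < 1:
            raise ConfigurationError("need at least one user per cohort")
        if self.days_before < 1 or self.days_after < 1:
            raise ConfigurationError("window lengths must be >= 1")
        if self.posts_per_user_day <= 0:
            raise ConfigurationError("posts_per_user_day must be positive")
        lo, hi = self.tokens_per_post
        if lo < 1 or hi < lo:
            raise ConfigurationError("tokens_per_post must be a valid positive range")
        if not self.category_base_rates:
            lex = Lexicon.from_dic(default_lexicon_path())
            object.__setattr__(self, "category_base_rates",
                               {cat: _DEFAULT_BASE_RATE for cat in lex.categories})
        total = 0.0
        for cat, p in self.category_base_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"base rate for {cat!r} not in [0, 1]: {p}")
            lift = self.injected_lifts.get(cat, 0.0)
            if lift < 0.0:
                raise ConfigurationError(f"lift for {cat!r} must be >= 0: {lift}")
            if p * (1.0 + lift) > 1.0:
                raise ConfigurationError(
                    f"base_rate * (1 + lift) > 1 for category {cat!r}")
            total += p * (1.0 + lift)
        if total >= 1.0:
            raise ConfigurationError(
                "lifted category probabilities leave no mass for filler words")
        unknown = set(self.injected_lifts) - set(self.category_base_rates)
        if unknown:
            raise ConfigurationError(f"lift on unknown categories: {sorted(unknown)}")
        if abs(sum(self.gender_mix) - 1.0) > 1e-9:
            raise ConfigurationError("gender_mix proportions must sum to 1")
        if self.n_communities < 1:
            raise ConfigurationError("n_communities must be >= 1")
        if not 0.0 <= self.active_prob <= 1.0:
            raise ConfigurationError("active_prob must be in [0, 1]")


@dataclass(frozen=True)
class UserTruth:
    user_id: str
    role: str               # target | baseline
    gender: str             # female | male | unknown
    name_ambiguous: bool
    display_name: str
    community: int
    follower_count: int
    day0: date


@dataclass(frozen=True)
class GroundTruth:
    """Generator-known labels for every synthetic user."""

    users: dict[str, UserTruth]
    lifts: dict[str, float]
    campaign_account: str
    campaign_retweet_counts: tuple[int, ...]
    campaign_like_counts: tuple[int, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lifts": self.lifts,
            "campaign_account": self.campaign_account,
            "campaign_retweet_counts": list(self.campaign_retweet_counts),
            "campaign_like_counts": list(self.campaign_like_counts),
            "users": {uid: {**asdict(u), "day0": u.day0.isoformat()}
                      for uid, u in self.users.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        users = {uid: UserTruth(**{**rec, "day0": date.fromisoformat(rec["day0"])})
                 for uid, rec in payload["users"].items()}
        return cls(users=users, lifts=payload["lifts"],
                   campaign_account=payload["campaign_account"],
                   campaign_retweet_counts=tuple(payload["campaign_retweet_counts"]),
                   campaign_like_counts=tuple(payload["campaign_like_counts"]))


def _user_ids(config: GeneratorConfig) -> list[str]:
    return ([f"t{i:05d}" for i in range(config.n_target_users)]
            + [f"b{i:05d}" for i in range(config.n_baseline_users)])


def _communities(config: GeneratorConfig) -> dict[str, int]:
    """Contiguous, near-equal planted blocks over all users."""
    ids = _user_ids(config)
    n, k = len(ids), config.n_communities
    if k > n:
        raise ConfigurationError("more communities than users")
    return {uid: (i * k) // n for i, uid in enumerate(ids)}


def _category_vocab(lexicon: Lexicon) -> dict[str, list[str]]:
    """Literal entries belonging to exactly one category, per category."""
    vocab = {}
    for cat in lexicon.categories:
        words = [w for w in sorted(lexicon.literals[cat]) if lexicon.match(w) == (cat,)]
        if not words:
            raise ConfigurationError(f"category {cat!r} has no unique literal entries")
        vocab[cat] = words
    return vocab


def generate_corpus(config: GeneratorConfig,
                    lexicon: Lexicon | None = None,
                    name_dict: NameDictionary | None = None,
                    ) -> tuple[list[Post], GroundTruth]:
    """Generate a corpus and its ground truth; byte-identical for a seed.

    Posts are ordered by (user, day, sequence).  Each target user's day-0
    engagement is a retweet of the campaign account containing one campaign
    keyword; each control user's first post carries one diet/health marker
    term.  Per-token category probabilities are ``base_rate`` everywhere
    except target users from day 0 onward, where they become
    ``base_rate * (1 + lift)``.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = lexicon or Lexicon.from_dic(default_lexicon_path())
    name_dict = name_dict or NameDictionary.from_tsv()
    vocab = _category_vocab(lexicon)
    cats = [c for c in lexicon.categories if c in config.category_base_rates]
    missing = set(config.category_base_rates) - set(cats)
    if missing:
        raise ConfigurationError(f"base rates for categories not in lexicon: {sorted(missing)}")
    surnames = default_surnames()
    campaign_terms = [t.lower() for t in default_campaign_terms()]
    communities = _communities(config)

    ids = _user_ids(config)
    n_users = len(ids)
    n_t = config.n_target_users
    roles = ["target"] * n_t + ["baseline"] * config.n_baseline_users

    # --- per-user attributes -------------------------------------------------
    gender_idx = rng.choice(3, size=n_users, p=list(config.gender_mix))
    genders = np.array(["female", "male", "unknown"])[gender_idx]
    followers = np.maximum(1, rng.lognormal(mean=5.8, sigma=1.6, size=n_users)).astype(int)
    f_pool = sorted(name_dict.female_names - name_dict.male_names)
    m_pool = sorted(name_dict.male_names - name_dict.female_names)
    amb_pool = sorted(name_dict.female_names & name_dict.male_names)
    display_names, ambiguous_flags = [], []
    for i in range(n_users):
        g = genders[i]
        if g == "unknown":
            display_names.append(f"user{rng.integers(10**6, 10**7)}")
            ambiguous_flags.append(False)
        else:
            ambiguous = bool(amb_pool) and rng.random() < config.ambiguous_name_frac
            pool = amb_pool if ambiguous else (f_pool if g == "female" else m_pool)
            first = pool[rng.integers(len(pool))]
            last = surnames[rng.integers(len(surnames))]
            display_names.append(f"{first.capitalize()} {last.capitalize()}")
            ambiguous_flags.append(ambiguous)

    day0_offsets = np.where(
        np.arange(n_users) < n_t,
        rng.integers(0, config.campaign_week_days, size=n_users), 0)
    day0s = [config.campaign_start + timedelta(days=int(o)) for o in day0_offsets]

    # --- per-user-day post counts -------------------------------------------
    n_days = config.days_before + config.days_after
    counts = rng.poisson(config.posts_per_user_day, size=(n_users, n_days))
    active = rng.random(n_users) < config.active_prob
    db = config.days_before
    for i in np.flatnonzero(active):
        for lo, hi in ((0, db), (db, n_days)):
            deficit = 3 - int(counts[i, lo:hi].sum())
            for _ in range(max(deficit, 0)):
                counts[i, lo + rng.integers(hi - lo)] += 1

    # --- flatten posts -------------------------------------------------------
    per_user = counts.sum(axis=1)
    post_user = np.repeat(np.arange(n_users), per_user)
    day_grid = np.tile(np.arange(-db, config.days_after), n_users)
    post_rel_day = np.repeat(day_grid, counts.ravel())
    n_posts = len(post_user)
    n_tok = rng.integers(config.tokens_per_post[0], config.tokens_per_post[1] + 1,
                         size=n_posts)

    # --- token category draws, split by regime -------------------------------
    base_p = np.array([config.category_base_rates[c] for c in cats])
    lift_p = base_p * (1.0 + np.array([config.injected_lifts.get(c, 0.0) for c in cats]))
    lifted = (post_user < n_t) & (post_rel_day >= 0)
    order = np.argsort(lifted, kind="stable")  # base block first, then lifted
    tok_per_regime = [int(n_tok[order][~lifted[order]].sum()),
                      int(n_tok[order][lifted[order]].sum())]
    words_parts = []
    for regime, (p_vec, total) in enumerate(zip((base_p, lift_p), tok_per_regime)):
        if total == 0:
            words_parts.append(np.empty(0, dtype=object))
            continue
        probs = np.append(p_vec, 1.0 - p_vec.sum())
        draw = rng.choice(len(cats) + 1, size=total, p=probs)
        words = np.empty(total, dtype=object)
        for k, cat in enumerate(cats):
            mask = draw == k
            if mask.any():
                wlist = vocab[cat]
                words[mask] = np.array(wlist, dtype=object)[
                    rng.integers(len(wlist), size=int(mask.sum()))]
        mask = draw == len(cats)
        if mask.any():
            words[mask] = np.array(FILLER_WORDS, dtype=object)[
                rng.integers(len(FILLER_WORDS), size=int(mask.sum()))]
        words_parts.append(words)
    all_words = np.concatenate(words_parts)

    # Reassemble texts in (base-block, lifted-block) post order, then emit
    # posts in canonical (user, day, sequence) order.
    boundaries = np.cumsum(n_tok[order])[:-1]
    texts_by_order = [" ".join(chunk) for chunk in np.split(all_words, boundaries)]
    texts = np.empty(n_posts, dtype=object)
    texts[order] = texts_by_order

    seconds = rng.integers(0, 86400, size=n_posts)
    rts = rng.poisson(0.3, size=n_posts)
    likes = rng.poisson(1.0, size=n_posts)

    # Control users carry one diet/health marker on their first post.
    first_post_idx: dict[int, int] = {}
    for idx in range(n_posts):
        u = int(post_user[idx])
        if u >= n_t and u not in first_post_idx:
            first_post_idx[u] = idx
    for u, idx in first_post_idx.items():
        marker = BASELINE_MARKERS[rng.integers(len(BASELINE_MARKERS))]
        texts[idx] = f"{texts[idx]} {marker}"

    posts: list[Post] = []
    for idx in range(n_posts):
        u = int(post_user[idx])
        d = day0s[u] + timedelta(days=int(post_rel_day[idx]))
        ts = datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(
            seconds=int(seconds[idx]))
        posts.append(Post(
            post_id=f"p{idx:08d}", user_id=ids[u], timestamp=ts, text=str(texts[idx]),
            is_retweet=False, retweeted_user_id=None,
            retweet_count=int(rts[idx]), like_count=int(likes[idx]),
            follower_count=int(followers[u]), display_name=display_names[u]))

    # Day-0 engagement post per target user (excluded from language scoring
    # downstream; its tokens are campaign keyword + fillers only).
    for u in range(n_t):
        kw = campaign_terms[rng.integers(len(campaign_terms))]
        fill = " ".join(np.array(FILLER_WORDS, dtype=object)[
            rng.integers(len(FILLER_WORDS), size=3)])
        d = day0s[u]
        ts = datetime(d.year, d.month, d.day, 12, 0, tzinfo=timezone.utc)
        posts.append(Post(
            post_id=f"c{u:08d}", user_id=ids[u], timestamp=ts,
            text=f"rt #{kw} {fill}", is_retweet=True,
            retweeted_user_id=config.campaign_account,
            retweet_count=0, like_count=0,
            follower_count=int(followers[u]), display_name=display_names[u]))

    # The campaign account's own content (for reach statistics).
    camp_rts = np.maximum(1, np.round(rng.lognormal(3.0, 1.0,
                          size=config.n_campaign_posts))).astype(int)
    camp_likes = np.maximum(1, np.round(rng.lognormal(3.7, 1.0,
                            size=config.n_campaign_posts))).astype(int)
    for j in range(config.n_campaign_posts):
        d = config.campaign_start + timedelta(days=int(j % config.campaign_week_days))
        ts = datetime(d.year, d.month, d.day, 9, 0, tzinfo=timezone.utc) + timedelta(
            minutes=int(j))
        kw = campaign_terms[j % len(campaign_terms)]
        posts.append(Post(
            post_id=f"a{j:08d}", user_id=config.campaign_account, timestamp=ts,
            text=f"join the #{kw} conversation this week", is_retweet=False,
            retweeted_user_id=None, retweet_count=int(camp_rts[j]),
            like_count=int(camp_likes[j]), follower_count=50000,
            display_name="NEDA Staff"))

    truth = GroundTruth(
        users={ids[i]: UserTruth(
            user_id=ids[i], role=roles[i], gender=str(genders[i]),
            name_ambiguous=ambiguous_flags[i], display_name=display_names[i],
            community=communities[ids[i]], follower_count=int(followers[i]),
            day0=day0s[i]) for i in range(n_users)},
        lifts=dict(config.injected_lifts),
        campaign_account=config.campaign_account,
        campaign_retweet_counts=tuple(int(v) for v in camp_rts),
        campaign_like_counts=tuple(int(v) for v in camp_likes),
    )
    return posts, truth


def generate_retweet_graph(config: GeneratorConfig) -> list[tuple[str, str, int]]:
    """Planted-partition retweet edge list (retweeter, author, count).

    Intra-community pairs connect with ``intra_edge_prob``, inter-community
    pairs with ``inter_edge_prob``; direction is random and counts are small.
    Uses an independent random stream so corpora and graphs can be generated
    in either order.
    """
    communities = _communities(config)  # validates n_communities <= n users
    ids = _user_ids(config)
    member = np.array([communities[u] for u in ids])
    rng = np.random.default_rng([config.seed, 929])
    n = len(ids)
    edges: list[tuple[str, str, int]] = []
    iu, ju = np.triu_indices(n, k=1)
    same = member[iu] == member[ju]
    p = np.where(same, config.intra_edge_prob, config.inter_edge_prob)
    hit = rng.random(len(iu)) < p
    flip = rng.random(len(iu)) < 0.5
    counts = 1 + rng.poisson(0.3, size=len(iu))
    for a, b, fl, c in zip(iu[hit], ju[hit], flip[hit], counts[hit]):
        src, dst = (ids[b], ids[a]) if fl else (ids[a], ids[b])
        edges.append((src, dst, int(c)))
    return edges


def retweet_posts_from_edges(edges: Sequence[tuple[str, str, int]],
                             start: date = date(2020, 2, 24)) -> list[Post]:
    """Minimal retweet posts realising an edge list (count c -> c retweets)."""
    posts = []
    k = 0
    for src, dst, count in edges:
        for _ in range(count):
            ts = datetime(start.year, start.month, start.day,
                          tzinfo=timezone.utc) + timedelta(minutes=k)
            posts.append(Post(
                post_id=f"e{k:08d}", user_id=src, timestamp=ts,
                text="rt spreading the word", is_retweet=True,
                retweeted_user_id=dst, retweet_count=0, like_count=0,
                follower_count=0, display_name=src))
            k += 1
    return posts
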