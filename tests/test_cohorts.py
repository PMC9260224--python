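from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from campaignimpact.cohorts import (build_cohorts, detect_day0,
                                    partition_window, normalize_terms)
from campaignimpact.errors import ConfigurationError

from conftest import make_post

CAMPAIGN = ["NEDAstaff", "NEDAwareness", "NEDA", "ComeAsYouAre", "SOSChat"]
BASELINE = ["diet", "health", "fitness"]


def test_detect_day0_earliest_match():
    posts = [make_post("loving NEDAwareness week", ts="2020-02-25T09:00:00"),
             make_post("more NEDAwareness", ts="2020-02-27T09:00:00")]
    assert detect_day0(posts, CAMPAIGN) == date(2020, 2, 25)


def test_detect_day0_no_match():
    posts = [make_post("just health talk", ts="2020-02-25T09:00:00")]
    assert detect_day0(posts, CAMPAIGN) is None
    assert detect_day0([], CAMPAIGN) is None


def test_detect_day0_unsorted_input():
    posts = [make_post("#ComeAsYouAre story", ts="2020-02-26T08:00:00"),
             make_post("loving #NEDAwareness week", ts="2020-02-24T22:00:00")]
    assert detect_day0(posts, CAMPAIGN) == date(2020, 2, 24)


def test_detect_day0_token_not_substring():
    # "kneaded" must not fire the "NEDA" keyword: matching is whole-token
    posts = [make_post("kneaded dough all day", ts="2020-02-24T10:00:00")]
    assert detect_day0(posts, CAMPAIGN) is None
    assert detect_day0([make_post("@NEDA hi", ts="2020-02-24T10:00:00")],
                       CAMPAIGN) == date(2020, 2, 24)


def test_normalize_terms_strips_prefixes():
    assert normalize_terms(["#NEDA", "@SOSChat", "Diet "]) == {"neda", "soschat", "diet"}


def test_partition_window_boundaries():
    day0 = date(2020, 3, 1)
    lower = make_post("x", ts="2020-02-15T00:00:00")     # day0 - 15
    upper = make_post("x", ts="2020-03-16T00:00:00")     # day0 + 15
    inside = make_post("x", ts="2020-03-01T23:59:59")    # day 0 itself
    pre, post = partition_window([lower, upper, inside], day0)
    assert pre == [lower]          # closed lower bound
    assert post == [inside]        # day 0 in post period; +15 excluded


def test_partition_window_excludes_campaign_post():
    day0 = date(2020, 3, 1)
    offsets = {-20: "x", -10: "x", -5: "x", 0: "NEDAwareness post", 2: "x", 16: "x"}
    posts = []
    for off, text in offsets.items():
        d = date(2020, 3, 1).toordinal() + off
        posts.append(make_post(text, ts=f"{date.fromordinal(d).isoformat()}T12:00:00",
                               post_id=f"off{off}"))
    pre, post = partition_window(posts, day0, campaign_terms=CAMPAIGN)
    assert [p.post_id for p in pre] == ["off-10", "off-5"]
    assert [p.post_id for p in post] == ["off2"]


def test_partition_window_negative_lengths_rejected():
    with pytest.raises(ConfigurationError):
        partition_window([], date(2020, 3, 1), days_before=-1)


def _user_posts(uid, n_pre, n_post, campaign_day="2020-02-25"):
    """n_pre/n_post ordinary posts around an engagement on campaign_day."""
    day0 = date.fromisoformat(campaign_day)
    posts = [make_post("I joined NEDAwareness", user_id=uid,
                       ts=f"{campaign_day}T08:00:00", post_id=f"{uid}-c")]
    for i in range(n_pre):
        d = date.fromordinal(day0.toordinal() - 1 - i)
        posts.append(make_post("daily note", user_id=uid, post_id=f"{uid}-pre{i}",
                               ts=f"{d.isoformat()}T10:00:00"))
    for i in range(n_post):
        d = date.fromordinal(day0.toordinal() + 1 + i % 13)
        posts.append(make_post("daily note", user_id=uid, post_id=f"{uid}-post{i}",
                               ts=f"{d.isoformat()}T10:{i:02d}:00"))
    return posts


def test_build_cohorts_eligibility_threshold():
    posts = (_user_posts("ok", 3, 3) + _user_posts("thin", 2, 10)
             + [make_post("tracking my diet today", user_id="ctl",
                          ts=f"2020-02-{10 + i}T09:00:00", post_id=f"ctl{i}")
                for i in range(6)]
             + [make_post("unrelated chatter", user_id="none",
                          ts="2020-02-20T09:00:00")])
    assignments = {a.user_id: a for a in build_cohorts(
        posts, CAMPAIGN, BASELINE, campaign_start=date(2020, 2, 24))}
    assert assignments["ok"].role == "target" and assignments["ok"].eligible
    # 2 pre-posts fail the >=3-per-window rule even with 10 post-posts
    assert not assignments["thin"].eligible
    assert assignments["thin"].n_pre == 2
    assert assignments["ctl"].role == "baseline"
    assert assignments["ctl"].day0 == date(2020, 2, 24)
    assert "none" not in assignments          # matches neither term set


def test_campaign_match_trumps_baseline():
    posts = [make_post("my diet and NEDAwareness story", user_id="both",
                       ts="2020-02-25T09:00:00")]
    (a,) = build_cohorts(posts, CAMPAIGN, BASELINE, date(2020, 2, 24))
    assert a.role == "target" and a.day0 == date(2020, 2, 25)


def test_no_user_in_both_cohorts():
    posts = _user_posts("t1", 4, 4) + [
        make_post("diet stuff", user_id="t1", ts="2020-02-20T10:00:00",
                  post_id="t1-diet")]
    assignments = build_cohorts(posts, CAMPAIGN, BASELINE, date(2020, 2, 24))
    assert [a.user_id for a in assignments] == ["t1"]


@settings(deadline=None, max_examples=30)
@given(n_pre=st.integers(0, 6), n_post=st.integers(0, 6), extra=st.integers(0, 4))
def test_eligibility_monotone_in_window_posts(n_pre, n_post, extra):
    """Adding posts inside a window never flips eligibility true -> false."""
    base = _user_posts("u", n_pre, n_post)
    more = _user_posts("u", n_pre + extra, n_post + extra)
    (a1,) = build_cohorts(base, CAMPAIGN, BASELINE, date(2020, 2, 24))
    (a2,) = build_cohorts(more, CAMPAIGN, BASELINE, date(2020, 2, 24))
    assert not (a1.eligible and not a2.eligible)


def test_cohort_recovery_matches_ground_truth(bundled_lexicon):
    from campaignimpact.synthetic import GeneratorConfig, generate_corpus
    cfg = GeneratorConfig(n_target_users=40, n_baseline_users=80, seed=21)
    posts, truth = generate_corpus(cfg)
    assignments = {a.user_id: a for a in build_cohorts(
        posts, CAMPAIGN, ["gym", "workout", "fitness", "selfcare"],
        cfg.campaign_start)}
    for uid, u in truth.users.items():
        assert assignments[uid].role == u.role
        if u.role == "target":
            assert assignments[uid].day0 == u.day0
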