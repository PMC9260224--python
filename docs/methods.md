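# Methods

`campaignimpact` measures how engaging with an online health-awareness
campaign changes what people subsequently write, using an event-aligned
counterfactual design. This note documents the statistical model, the
procedural conventions, the synthetic data the package validates itself on,
and the limits of what that validation shows.

## Study design

Each user who posted campaign vocabulary is anchored at **day 0**, the
calendar date (UTC) of their first campaign-matching post — a retweet of
campaign content or an original post containing a campaign keyword. Control
users posted on general diet/health vocabulary in the same span but never
matched a campaign term; they all share the campaign's first day as day 0.
Windows are half-open: the pre-period is `[day0 − B, day0)` and the
post-period `[day0, day0 + A)` with `B = A = 15` days by default. Day 0
belongs to the post-period because the engagement marks the start of
exposure. Users need at least `min_posts = 3` posts in *each* window to be
eligible (retweets count; the unit is simply posts).

Two deliberate conventions, both exposed as configuration switches:

* **The day-0 engagement post itself is excluded** from the post-period
  language series. The quantity of interest is continued self-expression;
  scoring the retweeted campaign text would mechanically inflate the
  measured change. The excluded post also does not count toward the
  eligibility threshold, so eligibility reflects a user's own continuing
  activity.
* **Retweeted text is scored as the retweeter's language** by default
  (`score_retweets`), on the view that choosing to amplify a message is
  itself expression.

Keyword matching is whole-token and case-insensitive after stripping `#`
and `@`, so a campaign acronym cannot fire inside an unrelated word.
Matching for cohort detection keeps @-mention bodies (addressing or
retweeting the campaign account is engagement); tokenisation for *language
scoring* removes URLs and mentions entirely, strips `#` but keeps hashtag
bodies, lowercases, splits on non-word characters, and keeps internal
apostrophes.

## Lexicon scoring

A category dictionary in the tab-separated `.dic` dialect (header of
`id<TAB>name` lines between `%` delimiters, then `word<TAB>id...` entries,
`*` as a trailing wildcard only) maps tokens to categories; a token may
count toward several. The **category rate** of a user-day is
`matching tokens / total tokens` over all of that user's posts that day.
The group-level series takes the *mean over users* of per-user daily rates
(each user weighted equally), so hyperactive accounts do not dominate. A
user with no posts on a day contributes nothing — silence is missing data,
not a zero rate. A group-day with no contributors at all is linearly
interpolated from its neighbours and flagged in the output.

The bundled `open_lexicon.dic` is a compact open stand-in covering nine
categories (Female, Anxiety, Risk, Money, Body, Health, Ingest, Friend,
Posemo); any dictionary in the same dialect, including proprietary ones the
user has licensed, can be substituted at every entry point. The category
set under analysis is configuration, not code.

## The counterfactual model

For each category, the target group's daily rate series `y_t` is modelled
against the control group's series `x_t` on the pre-period:

    y_t   = mu_t + beta * x_t + eps_t      eps_t ~ N(0, sigma_obs^2)
    mu_t+1 = mu_t + eta_t                  eta_t ~ N(0, sigma_lvl^2)

a local linear level plus a single static regression on the control. The
parameters `(sigma_obs, sigma_lvl, beta)` are estimated by maximising the
prediction-error-decomposition likelihood computed with a scalar Kalman
filter. The initial level is treated exactly-diffusely: conditioning on the
first observation gives `mu_0 | y_0 ~ N(y_0 − beta x_0, sigma_obs^2)`, and
that observation is excluded from the likelihood. Variances are optimised
on the log scale by Nelder–Mead from five deterministic starts (three
variance splits around the sample variance of `y`, and OLS / 0 / 1 starts
for `beta`), with fixed absolute simplex steps so the search is
translation-invariant in log-variance — which makes the whole fit exactly
equivariant under rescaling both series. Ties between starts are broken by
likelihood, then by smaller `sigma_lvl`. A constant-zero target series is
flagged non-estimable and the category is skipped with a logged reason.

This is a maximum-likelihood plug-in analogue of the Bayesian
structural-time-series ("causal impact") counterfactual. With exactly one
control covariate the spike-and-slab covariate selection of the Bayesian
formulation collapses to a scalar coefficient, and plugging in the MLE
keeps the procedure deterministic and dependency-light. The trade-off is
that parameter uncertainty is not propagated: with a 15-point pre-period
the intervals are mildly anticonservative (simulated interval coverage of a
planted effect is ≈ 0.9 at the 95% level rather than 0.95 — measured by the
test suite's recovery study, and the reason the package's own acceptance
bar for coverage is 0.85).

**Counterfactual simulation.** `n_sim` (default 1000) post-period
trajectories are drawn: the level starts from the terminal filtered
distribution `N(a_T, P_T)`, propagates with fresh level shocks, and adds
`beta * x_t` plus fresh observation noise. The effect summary compares the
observed post-period sum `S_obs` with the simulated sums:

* relative effect `= (S_obs − S_cf) / S_cf`, `S_cf` the mean predicted sum;
* interval: the same ratio applied to the central `interval_level`
  quantiles of the simulated sums;
* p-value: the tail-area share of draws at least as extreme — on either
  side of the simulated median — as the observation, with a +1/+1
  correction so it is never zero. The two-sided extremity definition is
  what keeps the false-positive rate at its nominal level (a directional
  one-sided tail rejects twice as often under the null); the measured
  type-I error at 0.05 is ≈ 0.06 over hundreds of null simulations.

Significance is flagged at the family-wise `alpha` (default 0.05) and at
the Bonferroni-corrected per-test level `alpha / #categories` within each
group (with 51 categories, 0.05/51 ≈ 0.00098, i.e. the "p < 0.001" tier).
Each category×group pair derives its own seed from the run seed, so adding
a category never perturbs another's draws. Estimation runs on group-mean
series (one response, one control per category×group), not per-user;
per-user estimation and seasonal components are out of scope — a 15+15-day
window under-identifies weekly seasonality.

## Gender labelling

Accounts are labelled `female` / `male` / `unknown` from display names
alone. Normalisation splits camel-case boundaries, drops every non-letter
character, and lowercases. Precedence: (1) the first honorific token
("mrs", "mr", "ms", ...; ungendered titles like "dr" are deliberately not
in the map); (2) scanning left-to-right, the first token found in exactly
one of the two first-name lists — a token present in both lists is
ambiguous and contributes nothing; (3) otherwise unknown. Honorifics
override name hits because they are explicit self-description; first
position wins because display names lead with given names. The bundled
`names.tsv` is a compact open list in a documented `name<TAB>f|m` format
and is fully replaceable; the algorithm, not the dictionary, is the
artifact. The three-class scheme cannot represent non-binary identities,
and any name heuristic mislabels organisational accounts and pseudonyms;
shares produced this way are estimates of self-presented gender only.

## Reach metrics

The follower sum over participating accounts is reported as a hypothetical
maximum audience — follower overlap between accounts cannot be
deduplicated. Engagement comparisons use a hand-computed Welch t
(unequal-variance, Welch–Satterthwaite degrees of freedom) and
Mann–Whitney U (midrank ties, tie-corrected normal approximation with
continuity correction); both are verified against independent reference
implementations to 1e-8 in the test suite. The retweet network is directed
(retweeter → author, weight = retweet count, no self-loops); community
detection symmetrises it by summing weights — random-walk theory assumes an
undirected graph — and runs Walktrap (walk length 4, the algorithm's
original default, exposed as a flag) with the dendrogram cut at maximum
modularity, via python-igraph's deterministic implementation.

## Vocabulary contrasts

For a category of interest, tweets containing at least one category word
are split by author gender and each word scored with the Haldane–Anscombe
smoothed odds ratio `((a+½)/(b+½)) / ((c+½)/(d+½))` on per-tweet usage
counts — a word counts once per tweet, since "being used" is a per-tweet
notion; a `count_unit="token"` switch selects raw occurrence counts
instead. Smoothing keeps every OR finite and positive with zero cells.
Rankings exclude a small bundled stopword list by default. Contrasts are
computed over post-period tweets only — the language used after the
engagement is the object of study. Keyword-prevalence change over time
(e.g. `covid*`, `coronavirus`) uses a pooled-variance two-proportion
z-test across a split date.

## Synthetic corpora

The generator emulates exactly the structure the estimator assumes, with
known ground truth:

* per-user-day post counts ~ Poisson(`posts_per_user_day`, default 2.0); a
  configurable fraction of users (`active_prob`, default 0.9) is guaranteed
  ≥ 3 posts per window, so the activity filter has both retained and
  dropped users to act on;
* token streams are bags of words: each token is a category word with
  probability `base_rate` (default 0.04 per category) — lifted to
  `base_rate × (1 + lift)` for target users from day 0 onward — else a
  filler word; filler words match no lexicon entry, and each category's
  sampling vocabulary uses only words unique to that category, so injected
  lifts do not bleed between categories;
* each target user's day 0 is jittered uniformly over the campaign week,
  mirroring staggered first engagement, and carries exactly one campaign
  engagement post (a retweet of the campaign account); control users carry
  one diet/health marker term and zero campaign matches;
* display names are "First Last" draws from the bundled gendered name
  lists; a configurable fraction receives names present in both lists to
  exercise the ambiguity rule; "unknown" users get dictionary-free handles;
* the retweet graph is a planted partition (contiguous near-equal blocks;
  intra-community edge probability 0.25 vs 0.005 between, configurable);
* follower counts are log-normal (median ≈ 330), engagement counts of the
  campaign account's own posts log-normal with median ≈ 20.

Everything is deterministic for a fixed seed, byte-for-byte. The
generator's validation rejects configurations where
`base_rate × (1 + lift) > 1`, naming the offending category. The baseline
cohort's activity distribution is configuration, not assertion — nothing in
the design constrains what control users' posting should look like.

What the generator does **not** emulate: natural language (so tokenisation
robustness to real tweets is tested only on hand fixtures), engagement and
follower dynamics over time, bots, deduplication, or any dependence between
a user's gender and their text. Passing recovery tests therefore shows the
estimator recovers effects under its own assumptions at realistic sizes and
noise levels — not that those assumptions hold for any particular platform's
data.

## Self-validation and problem sizes

The package validates itself at these sizes, chosen to mirror a
medium-sized campaign cohort while keeping a full validation run on one
CPU in minutes: effect-recovery studies use 500 target + 1000 control
users over 15+15-day windows, 10–20 tokens per post, lifts of 10–30%
(coverage ≈ 0.9, median bias < 1 percentage point over 100 replicate
corpora); null calibration uses smaller 120+240-user corpora, every
category estimated on a no-lift corpus counting as one null test (type-I
≈ 0.06 at nominal 0.05 over 500+ tests). `scripts/acceptance.py` re-runs
the same studies end to end and writes the measured numbers.

## Numerical conventions

* Eligibility: `eligible ⇔ n_pre ≥ 3 ∧ n_post ≥ 3`, monotone in added
  window posts.
* Cumulative effect conservation is exact: the last cumulative value equals
  the sum of pointwise effects.
* OR ties break by descending total frequency, then lexicographically.
* The interval endpoints bracket the point estimate by construction (the
  simulated mean lies between the central quantiles).
* A counterfactual that sums to ≤ 0 (an empty category) is non-estimable,
  never a division by zero.
* Reports are byte-identical across reruns with the same inputs and seed:
  no timestamps, sorted JSON keys, plain-float serialisation.
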