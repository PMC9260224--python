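"""End-to-end study orchestration: corpus -> cohorts -> gender -> scoring ->
impact -> reach -> contrast -> consolidated report.

Every stage writes its artifact (CSV/JSON) into the output directory, and the
consolidated ``report.json`` is byte-identical across reruns with the same
inputs and seed (no timestamps, sorted keys, plain-float serialisation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cohorts as cohorts_mod
from . import contrast as contrast_mod
from . import gender as gender_mod
from . import impact as impact_mod
from . import lexicon as lexicon_mod
from . import reach as reach_mod
from ._resources import (default_baseline_terms, default_campaign_terms,
                         default_lexicon_path, read_term_list)
from .corpus import iter_jsonl_lenient, read_jsonl, REQUIRED_FIELDS
from .errors import ConfigurationError, CorpusFormatError

logger = logging.getLogger(__name__)

GROUPS = ("all", "female", "male", "unknown")


@dataclass(frozen=True)
class StudyConfig:
    """Single configuration object for a full study run."""

    corpus: str
    output_dir: str
    campaign_start: date
    lexicon: str | None = None
    names: str | None = None
    campaign_terms: list[str] = field(default_factory=default_campaign_terms)
    baseline_terms: list[str] = field(default_factory=default_baseline_terms)
    campaign_accounts: list[str] = field(default_factory=lambda: ["nedastaff"])
    days_before: int = 15
    days_after: int = 15
    min_posts: int = 3
    include_day0_post: bool = False
    score_retweets: bool = True
    n_sim: int = 1000
    interval_level: float = 0.95
    alpha: float = 0.05
    bonferroni: bool = True
    contrast_categories: list[str] = field(default_factory=list)
    top_k_words: int = 30
    prevalence_terms: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        if "campaign_start" in raw and isinstance(raw["campaign_start"], str):
            raw["campaign_start"] = date.fromisoformat(raw["campaign_start"])
        if "campaign_terms_file" in raw:
            raw["campaign_terms"] = read_term_list(raw.pop("campaign_terms_file"))
        if "baseline_terms_file" in raw:
            raw["baseline_terms"] = read_term_list(raw.pop("baseline_terms_file"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = {**asdict(self), "campaign_start": self.campaign_start.isoformat()}
        del payload["output_dir"]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def validate_corpus(path: str | Path) -> dict[str, Any]:
    """Schema-check a JSONL corpus line by line.

    Returns diagnostics (total lines, malformed count, first errors).  A
    nonzero malformed count logs a warning; more than 10% malformed raises
    :class:`CorpusFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"corpus file not found: {path}")
    total = malformed = 0
    errors: list[str] = []
    for lineno, post, err in iter_jsonl_lenient(path):
        total += 1
        if err is not None:
            malformed += 1
            if len(errors) < 10:
                errors.append(f"line {lineno}: {err}")
    diag = {"total": total, "malformed": malformed, "errors": errors,
            "required_fields": list(REQUIRED_FIELDS)}
    if total and malformed / total > 0.10:
        raise CorpusFormatError(
            f"{malformed}/{total} malformed lines exceeds the 10% tolerance")
    if malformed:
        logger.warning("%d/%d malformed corpus lines", malformed, total)
    return diag


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        val = float(obj)
        return None if np.isnan(val) else val  # strict-JSON null, not NaN
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Execute every stage in dependency order and return the report dict.

    Artifacts written under ``config.output_dir``: cohorts.csv, gender.csv,
    series.csv, impact.csv, impact_details.json, network.csv, reach.json,
    contrast_<category>.csv, report.json, report.md, manifest.json.
    Identical inputs + seed give a byte-identical report.
    """
    t_start = time.perf_counter()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = lexicon_mod.Lexicon.from_dic(config.lexicon or default_lexicon_path())
    ndict = gender_mod.NameDictionary.from_tsv(config.names)

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t_start)

    stage("ingest")
    posts = read_jsonl(config.corpus)

    stage("cohorts")
    assignments = cohorts_mod.build_cohorts(
        posts, config.campaign_terms, config.baseline_terms, config.campaign_start,
        min_posts=config.min_posts, days_before=config.days_before,
        days_after=config.days_after, include_day0_post=config.include_day0_post)
    cohorts_mod.assignments_to_frame(assignments).to_csv(outdir / "cohorts.csv", index=False)
    eligible = [a for a in assignments if a.eligible]
    logger.info("%d assigned users, %d eligible", len(assignments), len(eligible))

    stage("gender")
    display_names: dict[str, str] = {}
    for post in posts:
        display_names.setdefault(post.user_id, post.display_name)
    labels = {a.user_id: gender_mod.label_user(a.user_id, display_names[a.user_id], ndict)
              for a in assignments}
    pd.DataFrame([(l.user_id, l.label, l.evidence) for l in labels.values()],
                 columns=["user_id", "label", "evidence"]).to_csv(
        outdir / "gender.csv", index=False)
    shares, counts = gender_mod.gender_shares(labels.values())

    stage("score")
    day0_map = {a.user_id: a.day0 for a in eligible}
    exclude = set()
    if not config.include_day0_post:
        c_terms = cohorts_mod.normalize_terms(config.campaign_terms)
        by_user: dict[str, list] = {}
        for post in posts:
            if post.user_id in day0_map:
                by_user.setdefault(post.user_id, []).append(post)
        for uid, uposts in by_user.items():
            first = cohorts_mod.first_matching_post(uposts, c_terms)
            if first is not None:
                exclude.add(first.post_id)
    vectors = lexicon_mod.compute_day_vectors(
        posts, day0_map, lexicon, config.days_before, config.days_after,
        exclude_posts=exclude, score_retweets=config.score_retweets)

    role_of = {a.user_id: a.role for a in eligible}
    group_users: dict[str, dict[str, set[str]]] = {}
    for role in ("target", "baseline"):
        group_users[role] = {"all": set()}
        for g in ("female", "male", "unknown"):
            group_users[role][g] = set()
    for a in eligible:
        group_users[a.role]["all"].add(a.user_id)
        group_users[a.role][labels[a.user_id].label].add(a.user_id)

    series_list = []
    pairs = {}
    for grp in GROUPS:
        t_users = group_users["target"][grp]
        b_users = group_users["baseline"][grp]
        if not t_users or not b_users:
            logger.warning("group %r has an empty cohort; skipped", grp)
            continue
        for cat in lexicon.categories:
            t_series = lexicon_mod.build_series(vectors, cat, f"target:{grp}", t_users,
                                                config.days_before, config.days_after)
            b_series = lexicon_mod.build_series(vectors, cat, f"baseline:{grp}", b_users,
                                                config.days_before, config.days_after)
            series_list += [t_series, b_series]
            pairs[(cat, grp)] = (t_series, b_series)
    lexicon_mod.series_to_frame(series_list).to_csv(outdir / "series.csv", index=False)

    stage("impact")
    impact_cfg = impact_mod.ImpactModelConfig(
        n_sim=config.n_sim, interval_level=config.interval_level,
        alpha=config.alpha, bonferroni=config.bonferroni, seed=config.seed)
    impact_frame, impact_results = impact_mod.run_all_categories(pairs, impact_cfg)
    impact_frame.to_csv(outdir / "impact.csv", index=False)
    details = {f"{r.category}|{r.group}": {
        "pointwise": _jsonable(r.pointwise),
        "cumulative": _jsonable(r.cumulative),
        "counterfactual_mean": _jsonable(r.counterfactual_mean)}
        for r in impact_results}
    (outdir / "impact_details.json").write_text(
        json.dumps(details, sort_keys=True), encoding="utf-8")

    stage("reach")
    network = reach_mod.build_retweet_network(posts)
    nx_edges = [(u, v, d["weight"]) for u, v, d in network.edges(data=True)]
    pd.DataFrame(sorted(nx_edges), columns=["source", "target", "weight"]).to_csv(
        outdir / "network.csv", index=False)
    summary = reach_mod.reach_summary(posts, config.campaign_accounts)
    communities = None
    if network.number_of_nodes() > 0:
        communities = reach_mod.detect_communities(network)
    reach_payload = {
        "summary": _jsonable(asdict(summary)),
        "communities": None if communities is None else {
            "n_communities": len(communities.communities),
            "modularity": communities.modularity,
            "top_sizes": [len(c) for c in communities.top(5)],
        },
    }
    (outdir / "reach.json").write_text(
        json.dumps(reach_payload, sort_keys=True), encoding="utf-8")

    stage("contrast")
    contrast_cats = config.contrast_categories or [
        r.category for r in impact_results
        if r.group == "all" and r.significant_at != "none"][:3]
    post_period_posts: dict[str, list] = {"female": [], "male": []}
    day0_of = {a.user_id: a.day0 for a in eligible if a.role == "target"}
    for post in posts:
        d0 = day0_of.get(post.user_id)
        if d0 is None or post.post_id in exclude:
            continue
        if 0 <= (post.date - d0).days < config.days_after:
            lab = labels[post.user_id].label
            if lab in post_period_posts:
                post_period_posts[lab].append(post)
    contrast_out = {}
    for cat in contrast_cats:
        g1 = contrast_mod.category_tweet_filter(post_period_posts["female"], lexicon, cat)
        g2 = contrast_mod.category_tweet_filter(post_period_posts["male"], lexicon, cat)
        if not g1 or not g2:
            logger.warning("contrast for %r skipped: empty gender group", cat)
            continue
        top_f, top_m = contrast_mod.odds_ratio_ranking(g1, g2, top_k=config.top_k_words)
        pd.DataFrame([(e.word, e.a, e.b, e.c, e.d, e.odds_ratio)
                      for e in top_f + top_m],
                     columns=["word", "a", "b", "c", "d", "odds_ratio"]).to_csv(
            outdir / f"contrast_{cat.lower()}.csv", index=False)
        contrast_out[cat] = {
            "female_leaning": [(e.word, round(e.odds_ratio, 4)) for e in top_f[:10]],
            "male_leaning": [(e.word, round(e.odds_ratio, 4)) for e in top_m[:10]],
        }
    prevalence = None
    if config.prevalence_terms:
        test = contrast_mod.prevalence_z_test(posts, config.prevalence_terms,
                                              config.campaign_start)
        prevalence = _jsonable(asdict(test))

    stage("report")
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohorts": {
            "n_users_assigned": len(assignments),
            "n_target_eligible": len(group_users["target"]["all"]),
            "n_baseline_eligible": len(group_users["baseline"]["all"]),
        },
        "gender_shares_pct": {k: round(100 * v, 1) for k, v in shares.items()},
        "gender_counts": counts,
        "reach": reach_payload,
        "impact": _jsonable(impact_frame.to_dict(orient="records")),
        "bonferroni_corrected_level": impact_mod.bonferroni_level(
            config.alpha, len(lexicon.categories)),
        "contrast": contrast_out,
        "prevalence": prevalence,
    }
    report = _jsonable(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True), encoding="utf-8")
    (outdir / "report.md").write_text(_report_markdown(report), encoding="utf-8")
    (outdir / "manifest.json").write_text(json.dumps(
        {"config_hash": report["config_hash"], "seed": config.seed,
         "stages": ["ingest", "cohorts", "gender", "score", "impact",
                    "reach", "contrast", "report"]},
        indent=1, sort_keys=True), encoding="utf-8")
    logger.info("study complete in %.1fs", time.perf_counter() - t_start)
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Campaign impact report", ""]
    c = report["cohorts"]
    lines += [f"- users assigned: {c['n_users_assigned']}",
              f"- eligible target users: {c['n_target_eligible']}",
              f"- eligible control users: {c['n_baseline_eligible']}",
              ""]
    g = report["gender_shares_pct"]
    lines += [f"- gender shares: female {g['female']}%, male {g['male']}%, "
              f"unknown {g['unknown']}%", ""]
    lines += ["| category | group | relative effect | 95% interval | p | tier |",
              "|---|---|---|---|---|---|"]
    for row in report["impact"]:
        lines.append(
            f"| {row['category']} | {row['group']} | "
            f"{100 * row['relative_effect']:+.1f}% | "
            f"[{100 * row['ci_low']:+.1f}%, {100 * row['ci_high']:+.1f}%] | "
            f"{row['p_value']:.4f} | {row['tier']} |")
    lines.append("")
    return "\n".join(lines)
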