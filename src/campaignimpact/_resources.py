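"""Loaders for the word lists bundled with the package.

The shipped lexicon is a compact open stand-in covering the categories used
throughout the documentation (Female, Anxiety, Risk, Money, Body, Health,
Ingest, Friend, Posemo); any dictionary in the same ``.dic`` dialect can be
substituted for it at every entry point that takes a lexicon path.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

_PKG = "campaignimpact.data"


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files(_PKG).joinpath(name)))


def read_term_list(path: str | Path) -> list[str]:
    """Read a one-term-per-line UTF-8 word list, skipping blanks and # comments."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.strip()
        if term and not term.startswith("#"):
            out.append(term)
    return out


def default_lexicon_path() -> Path:
    return data_path("open_lexicon.dic")


def default_campaign_terms() -> list[str]:
    return read_term_list(data_path("campaign_terms.txt"))


def default_baseline_terms() -> list[str]:
    return read_term_list(data_path("baseline_terms.txt"))


def default_stopwords() -> frozenset[str]:
    return frozenset(read_term_list(data_path("stopwords.txt")))


def default_names_path() -> Path:
    return data_path("names.tsv")


def default_surnames() -> list[str]:
    return read_term_list(data_path("surnames.txt"))
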