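"""Name-based gender labelling of accounts.

Each account is labelled ``female``, ``male`` or ``unknown`` from its display
name alone: honorific tokens ("mrs", "mr", ...) take precedence, otherwise the
first name token found in exactly one of the two first-name lists decides, and
a token present in both lists is treated as ambiguous and contributes nothing.
This three-class scheme cannot represent non-binary identities and, like any
name heuristic, mislabels accounts whose display name is not a personal name;
the shares it produces are estimates of self-presented gender only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._resources import default_names_path
from .errors import EmptyInputError

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"
LABELS = (FEMALE, MALE, UNKNOWN)

#: Honorific token -> gender.  Ungendered titles (dr, prof, ...) are absent
#: on purpose: they carry no gender signal and must fall through to name lookup.
DEFAULT_HONORIFICS: dict[str, str] = {
    "mr": MALE,
    "mister": MALE,
    "sir": MALE,
    "mrs": FEMALE,
    "ms": FEMALE,
    "miss": FEMALE,
    "madam": FEMALE,
    "madame": FEMALE,
    "lady": FEMALE,
}


@dataclass(frozen=True)
class NameDictionary:
    """First-name lists plus honorific rules; overlap resolved at lookup time."""

    female_names: frozenset[str]
    male_names: frozenset[str]
    honorifics: Mapping[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.honorifics is None:
            object.__setattr__(self, "honorifics", dict(DEFAULT_HONORIFICS))

    @classmethod
    def from_tsv(cls, path: str | Path | None = None,
                 honorifics: Mapping[str, str] | None = None) -> "NameDictionary":
        """Load a two-column ``name<TAB>f|m`` list (defaults to the bundled one)."""
        path = default_names_path() if path is None else Path(path)
        female, male = set(), set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, tag = line.partition("\t")
            name, tag = name.strip().lower(), tag.strip().lower()
            if tag in ("f", "female"):
                female.add(name)
            elif tag in ("m", "male"):
                male.add(name)
            else:
                raise ValueError(f"bad gender tag {tag!r} for name {name!r}")
        return cls(frozenset(female), frozenset(male),
                   dict(DEFAULT_HONORIFICS) if honorifics is None else dict(honorifics))


@dataclass(frozen=True)
class GenderLabel:
    user_id: str
    label: str          # female | male | unknown
    evidence: str       # honorific | name_match | none

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")
        if self.evidence == "none" and self.label != UNKNOWN:
            raise ValueError("evidence 'none' requires label 'unknown'")


_CAMEL_BOUNDARY = re.compile(r"(?<=[a-z])(?=[A-Z])")


def normalize_name(display_name: str) -> list[str]:
    """Lowercased word tokens of a display name.

    Camel-case boundaries become splits, then every non-letter character
    (emoji, digits, punctuation) is dropped.  Total function: any input maps
    to a (possibly empty) token list.
    """
    spaced = _CAMEL_BOUNDARY.sub(" ", display_name)
    cleaned = "".join(ch if ch.isalpha() or ch.isspace() else " " for ch in spaced)
    return cleaned.lower().split()


def infer_gender(tokens: Sequence[str], ndict: NameDictionary) -> tuple[str, str]:
    """(label, evidence) for normalized name tokens.

    Precedence: first honorific token; else first token in exactly one name
    list (left-to-right, because display names lead with given names); a token
    in both lists is ambiguous and skipped; else unknown.
    """
    for tok in tokens:
        hit = ndict.honorifics.get(tok)
        if hit is not None:
            return hit, "honorific"
    for tok in tokens:
        in_f = tok in ndict.female_names
        in_m = tok in ndict.male_names
        if in_f and in_m:
            continue  # ambiguity rule: contributes no label
        if in_f:
            return FEMALE, "name_match"
        if in_m:
            return MALE, "name_match"
    return UNKNOWN, "none"


def label_user(user_id: str, display_name: str, ndict: NameDictionary) -> GenderLabel:
    label, evidence = infer_gender(normalize_name(display_name), ndict)
    return GenderLabel(user_id=user_id, label=label, evidence=evidence)


def label_users(display_names: Mapping[str, str], ndict: NameDictionary) -> dict[str, GenderLabel]:
    """Label every user_id -> display_name entry; deterministic."""
    return {uid: label_user(uid, name, ndict) for uid, name in display_names.items()}


def gender_shares(labels: Iterable[GenderLabel | str]) -> tuple[dict[str, float], dict[str, int]]:
    """(shares, counts) over female/male/unknown for the supplied unit.

    The unit is whatever the caller passes one label per — accounts, or tweets
    when weighting accounts by activity.  Shares sum to 1 exactly up to float
    rounding; report-level percentages round to one decimal.
    """
    counts = {lab: 0 for lab in LABELS}
    n = 0
    for item in labels:
        lab = item.label if isinstance(item, GenderLabel) else item
        counts[lab] += 1
        n += 1
    if n == 0:
        raise EmptyInputError("gender_shares requires at least one label")
    shares = {lab: counts[lab] / n for lab in LABELS}
    return shares, counts


def shares_from_counts(female: int, male: int, unknown: int) -> dict[str, float]:
    """Shares from pre-tallied counts (convenience for published tables)."""
    total = female + male + unknown
    if total == 0:
        raise EmptyInputError("all counts are zero")
    return {FEMALE: female / total, MALE: male / total, UNKNOWN: unknown / total}
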