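"""Mining hazard ratios and confidence intervals from abstract text.

This module implements the corpus-building front end of the prior-elicitation
pipeline: journal-name normalization, allocation of articles to biomedical
subfields via top-journal lists, regex extraction of the first complete
``HR (level% CI lower–upper)`` tuple from each abstract, validity screening of
extracted tuples, and retention-rate diagnostics across the pipeline steps.

Extraction is deliberately conservative: a tuple is used only when the hazard
ratio, the confidence level, and both interval bounds are all present.
Hazard ratios reported with a p-value instead of an interval are ignored, as
are later matches in the same abstract (main findings are conventionally
reported first).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "ArticleRecord",
    "ExtractedEffect",
    "ScreenReport",
    "normalize_journal_name",
    "build_subfield_index",
    "allocate_subfields",
    "extract_first_effect",
    "screen_effect",
    "retention_table",
]


@dataclass(frozen=True)
class ArticleRecord:
    """One literature-database record: identifier, raw journal name, abstract."""

    article_id: str
    journal_raw: str
    abstract: str


@dataclass(frozen=True)
class ExtractedEffect:
    """A mined hazard ratio with its confidence interval.

    ``decimals_*`` record the number of printed decimal places of each number
    at parse time; they drive the rounding tolerance used by
    :func:`screen_effect`.
    """

    hr: float
    level: float
    hr_lower: float
    hr_upper: float
    decimals_hr: int
    decimals_lower: int
    decimals_upper: int


#: Reason codes emitted by :func:`screen_effect`.
LEVEL_RANGE = "LEVEL_RANGE"
NONPOSITIVE = "NONPOSITIVE"
MIDPOINT = "MIDPOINT"
BOUND_COLLISION = "BOUND_COLLISION"


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the validity checks; ``passed`` iff no reason codes."""

    passed: bool
    reason_codes: tuple[str, ...] = field(default_factory=tuple)


_AMP_RE = re.compile(r"&amp;|&")
_NON_ALPHA_RE = re.compile(r"[^A-Za-z\s]")
_WS_RE = re.compile(r"\s+")


def normalize_journal_name(raw: str) -> str:
    """Canonicalize a journal name for cross-database matching.

    Applies, in order: replace ampersands (literal ``&`` and the HTML entity
    ``&amp;``) with ``AND``; strip every character that is neither alphabetic
    nor whitespace; move a trailing ``The`` (the remnant of ``", The"``) to the
    front; collapse whitespace; uppercase.  Idempotent.

    >>> normalize_journal_name("Lancet Oncology, The")
    'THE LANCET ONCOLOGY'
    >>> normalize_journal_name("Heart & Lung")
    'HEART AND LUNG'
    """
    s = _AMP_RE.sub(" AND ", raw)
    s = _NON_ALPHA_RE.sub("", s)
    words = _WS_RE.sub(" ", s).strip().split(" ")
    if len(words) > 1 and words[-1].lower() == "the":
        words = [words[-1]] + words[:-1]
    return " ".join(words).upper()


def build_subfield_index(journal_lists: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Turn a (subfield, journal) table into subfield -> canonical-name sets.

    A journal may appear under several subfields (shared top journals).
    """
    index: dict[str, set[str]] = {}
    for subfield, journal in zip(journal_lists["subfield"], journal_lists["journal"]):
        index.setdefault(str(subfield), set()).add(normalize_journal_name(str(journal)))
    return {k: frozenset(v) for k, v in index.items()}


def allocate_subfields(
    record: ArticleRecord, index: Mapping[str, frozenset[str]]
) -> set[str]:
    """Subfields whose top-journal list contains the article's journal.

    May be empty (journal in no list) or contain several subfields (journal
    shared between lists).
    """
    canonical = normalize_journal_name(record.journal_raw)
    return {name for name, journals in index.items() if canonical in journals}


# Grammar for one complete reported tuple.  Head tokens cover the printed
# variants "hazard ratio", "hazards ratios", "hazard ratio (HR)", "HR",
# "H.R."; "=" or ":" with optional spaces; the interval introduced by
# "95% CI" or "CI 95%" (also "confidence interval"); bounds separated by
# hyphen/dash, "to", or comma.  Decimal point only.
_NUM = r"\d+(?:\.\d+)?"
_CI_WORD = r"(?:c\.?i\.?|confidence\s+intervals?)"
_EFFECT_RE = re.compile(
    rf"""
    (?<![A-Za-z])
    (?:hazards?\s+ratios?(?:\s*[\(\[]\s*h\.?r\.?\s*[\)\]])?|h\.r\.|hr(?![A-Za-z]))
    \s*[=:]\s*
    (?P<hr>{_NUM})
    \s*[,;]?\s*[\(\[]?\s*
    (?:
        (?P<lvl1>{_NUM})\s*%\s*{_CI_WORD}
      | {_CI_WORD}\s*[:=,]?\s*(?P<lvl2>{_NUM})\s*%
    )
    \s*[:=,]?\s*
    (?P<lower>{_NUM})
    \s*(?:-|–|—|‐|to|,)\s*
    (?P<upper>{_NUM})
    """,
    re.IGNORECASE | re.VERBOSE,
)


def _decimals(token: str) -> int:
    return len(token.partition(".")[2])


def extract_first_effect(abstract: str) -> Optional[ExtractedEffect]:
    """First complete (HR, level, lower, upper) tuple in reading order.

    Returns ``None`` when no complete tuple exists; an HR followed by a
    p-value only, or an "HR" abbreviation without an interval, never yields a
    match.  "First match" means the first *complete* tuple — a partial leading
    mention does not veto a valid later result.
    """
    m = _EFFECT_RE.search(abstract)
    if m is None:
        return None
    level = m.group("lvl1") or m.group("lvl2")
    return ExtractedEffect(
        hr=float(m.group("hr")),
        level=float(level),
        hr_lower=float(m.group("lower")),
        hr_upper=float(m.group("upper")),
        decimals_hr=_decimals(m.group("hr")),
        decimals_lower=_decimals(m.group("lower")),
        decimals_upper=_decimals(m.group("upper")),
    )


def midpoint_tolerance(e: ExtractedEffect) -> float:
    """Half-ULP rounding tolerance for the log-midpoint check.

    First-order propagation of rounding each printed number to its recorded
    decimals through the log transform: rounding HR at d decimals perturbs
    log HR by at most 0.5·10^-d / HR, and each bound enters the midpoint with
    weight 1/2.
    """
    return 0.5 * 10.0**-e.decimals_hr / e.hr + 0.25 * (
        10.0**-e.decimals_lower / e.hr_lower + 10.0**-e.decimals_upper / e.hr_upper
    )


def screen_effect(e: ExtractedEffect) -> ScreenReport:
    """Validity checks on one extracted tuple.

    Fails ``LEVEL_RANGE`` unless 0 < level < 100; ``NONPOSITIVE`` unless HR and
    both bounds are strictly positive; ``MIDPOINT`` unless log HR lies within
    the rounding tolerance of the midpoint of the log bounds (an inverted
    interval, lower > upper, also fails here — the midpoint relation for an
    ordered interval is malformed); ``BOUND_COLLISION`` when the printed HR
    equals a printed bound (a rounding artifact that would make the interval
    degenerate on one side).
    """
    codes: list[str] = []
    if not 0.0 < e.level < 100.0:
        codes.append(LEVEL_RANGE)
    if not (e.hr > 0.0 and e.hr_lower > 0.0 and e.hr_upper > 0.0):
        codes.append(NONPOSITIVE)
    else:
        if e.hr_lower > e.hr_upper:
            codes.append(MIDPOINT)
        else:
            mid = 0.5 * (math.log(e.hr_lower) + math.log(e.hr_upper))
            if abs(math.log(e.hr) - mid) > midpoint_tolerance(e):
                codes.append(MIDPOINT)
        if e.hr == e.hr_lower or e.hr == e.hr_upper:
            codes.append(BOUND_COLLISION)
    return ScreenReport(passed=not codes, reason_codes=tuple(codes))


def retention_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-(subfield, journal) retention proportions across pipeline steps.

    ``counts`` has columns ``subfield, journal, allocated, matched,
    considered``.  Returns the same keys with ``S1 = matched/allocated`` and
    ``S2 = considered/matched``; rows with a zero denominator (allocated or
    matched equal to 0) are dropped.
    """
    required = {"subfield", "journal", "allocated", "matched", "considered"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    kept = counts[(counts["allocated"] > 0) & (counts["matched"] > 0)].copy()
    kept["S1"] = kept["matched"] / kept["allocated"]
    kept["S2"] = kept["considered"] / kept["matched"]
    return kept[["subfield", "journal", "S1", "S2"]].reset_index(drop=True)
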