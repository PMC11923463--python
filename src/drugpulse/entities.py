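"""Lexicon-based entity extraction, normalization, and the accuracy harness.

The matcher is case-insensitive, word-boundary anchored, longest-match-first
with left-to-right tie-breaking; multiword surfaces are supported. An
external model tagger can be registered as a hook; its output is normalized
through the same lexicon, and surfaces the lexicon cannot map are dropped
(counted) because downstream stages require canonical concepts.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .corpus_io import TweetRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_DRUG_MENTIONS = 1000
DEFAULT_MIN_SYMPTOM_MENTIONS = 250


class LexiconError(ValueError):
    """Raised for conflicting or malformed lexicon entries."""


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    concept_class: str  # "drug" | "symptom"
    atc_code: Optional[str] = None

    def __post_init__(self):
        if not self.surface or not self.surface.strip():
            raise LexiconError("empty surface form")
        if self.concept_class not in ("drug", "symptom"):
            raise LexiconError(f"unknown concept class {self.concept_class!r}")


@dataclass(frozen=True)
class EntityMention:
    """A normalized entity occurrence located in one tweet.

    ``span`` is 0-based, half-open in character offsets of the tweet text.
    """

    tweet_id: str
    start: int
    end: int
    surface: str
    canonical: str
    concept_class: str


def load_lexicon(path) -> list:
    """Read a lexicon CSV with header surface,canonical,class[,atc]."""
    entries = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                LexiconEntry(
                    surface=row["surface"],
                    canonical=row["canonical"],
                    concept_class=row["class"],
                    atc_code=row.get("atc") or None,
                )
            )
    return entries


def write_lexicon(entries: Iterable[LexiconEntry], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "canonical", "class", "atc"])
        for e in entries:
            writer.writerow([e.surface, e.canonical, e.concept_class, e.atc_code or ""])


class Matcher:
    """Scanner over lexicon surfaces.

    A single alternation regex with alternatives ordered longest-first gives
    longest-match-at-position semantics; the scan then resumes after the
    match, so spans never overlap.
    """

    def __init__(self, lexicon: Sequence[LexiconEntry]):
        by_surface: dict = {}
        self.atc: dict = {}
        self.class_of: dict = {}
        for entry in lexicon:
            key = entry.surface.lower()
            if key in by_surface:
                prev = by_surface[key]
                if prev.canonical != entry.canonical:
                    raise LexiconError(
                        f"surface {entry.surface!r} maps to both "
                        f"{prev.canonical!r} and {entry.canonical!r}"
                    )
                continue
            prior_class = self.class_of.get(entry.canonical)
            if prior_class is not None and prior_class != entry.concept_class:
                raise LexiconError(
                    f"canonical {entry.canonical!r} appears with two classes"
                )
            by_surface[key] = entry
            self.class_of[entry.canonical] = entry.concept_class
            if entry.atc_code:
                self.atc[entry.canonical] = entry.atc_code
        self._by_surface = by_surface
        surfaces = sorted(by_surface, key=len, reverse=True)
        if surfaces:
            pattern = r"\b(?:" + "|".join(re.escape(s) for s in surfaces) + r")\b"
            self._regex = re.compile(pattern, re.IGNORECASE)
        else:
            self._regex = None

    def normalize(self, surface: str) -> Optional[LexiconEntry]:
        return self._by_surface.get(surface.lower())

    def atc_map(self) -> dict:
        return dict(self.atc)

    def find(self, tweet_id: str, text: str) -> list:
        if self._regex is None:
            return []
        mentions = []
        for match in self._regex.finditer(text):
            entry = self._by_surface[match.group(0).lower()]
            mentions.append(
                EntityMention(
                    tweet_id=tweet_id,
                    start=match.start(),
                    end=match.end(),
                    surface=match.group(0),
                    canonical=entry.canonical,
                    concept_class=entry.concept_class,
                )
            )
        return mentions


def build_matcher(lexicon: Sequence[LexiconEntry]) -> Matcher:
    return Matcher(lexicon)


def extract_mentions(record: TweetRecord, matcher: Matcher) -> list:
    """All lexicon matches in a tweet, ordered by span start."""
    return matcher.find(record.tweet_id, record.text)


def extract_corpus(records: Iterable[TweetRecord], matcher: Matcher) -> list:
    mentions = []
    for rec in records:
        mentions.extend(extract_mentions(rec, matcher))
    return mentions


class ModelTaggerHook:
    """Pluggable external tagger; falls back to the lexicon matcher.

    A registered tagger maps a record to raw ``(start, end, surface)`` spans;
    these are normalized through the lexicon and unmapped surfaces are
    dropped with a counter.
    """

    def __init__(self, matcher: Matcher, tagger: Optional[Callable] = None):
        self.matcher = matcher
        self.tagger = tagger
        self.n_unmapped = 0

    def __call__(self, record: TweetRecord) -> list:
        if self.tagger is None:
            logger.info("no external tagger registered; using lexicon matcher")
            return extract_mentions(record, self.matcher)
        mentions = []
        for start, end, surface in self.tagger(record):
            entry = self.matcher.normalize(surface)
            if entry is None:
                self.n_unmapped += 1
                continue
            mentions.append(
                EntityMention(
                    tweet_id=record.tweet_id,
                    start=start,
                    end=end,
                    surface=surface,
                    canonical=entry.canonical,
                    concept_class=entry.concept_class,
                )
            )
        mentions.sort(key=lambda m: m.start)
        return mentions


def mention_counts(mentions: Iterable[EntityMention]) -> Counter:
    return Counter(m.canonical for m in mentions)


def frequency_filter(
    counts: Mapping[str, int],
    class_of: Mapping[str, str],
    min_drug: int = DEFAULT_MIN_DRUG_MENTIONS,
    min_symptom: int = DEFAULT_MIN_SYMPTOM_MENTIONS,
) -> set:
    """Strictly-more-than thresholds per class (defaults 1000 / 250)."""
    retained = set()
    for canonical, count in counts.items():
        cls = class_of.get(canonical)
        if cls == "drug" and count > min_drug:
            retained.add(canonical)
        elif cls == "symptom" and count > min_symptom:
            retained.add(canonical)
    return retained


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = methods, columns = correct/incorrect."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("row sums must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_yates(table: ContingencyTable2x2):
    """Yates-continuity-corrected chi-square statistic at df=1.

    statistic = sum over the 4 cells of (|O - E| - 0.5)^2 / E, with expected
    counts from the row/column margins.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    expected = np.outer(row, col) / total
    if (expected == 0).any():
        raise ValueError("chi-square undefined: an expected cell count is 0")
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    return statistic, 1


@dataclass
class ExtractionEvaluation:
    accuracy_a: float
    accuracy_b: float
    table: ContingencyTable2x2
    statistic: float
    df: int = 1


def evaluate_extraction(
    pred_a: Sequence, pred_b: Sequence, gold: Sequence
) -> ExtractionEvaluation:
    """Accuracy of two label vectors against gold, plus the Yates chi-square
    over the per-method correct/incorrect contingency table."""
    if not (len(pred_a) == len(pred_b) == len(gold)):
        raise ValueError("label vectors must be aligned and equal length")
    n = len(gold)
    if n == 0:
        raise ValueError("empty evaluation set")
    correct_a = sum(1 for p, g in zip(pred_a, gold) if p == g)
    correct_b = sum(1 for p, g in zip(pred_b, gold) if p == g)
    table = ContingencyTable2x2(correct_a, n - correct_a, correct_b, n - correct_b)
    statistic, df = chi_square_yates(table)
    return ExtractionEvaluation(
        accuracy_a=correct_a / n,
        accuracy_b=correct_b / n,
        table=table,
        statistic=statistic,
        df=df,
    )


def write_mentions(mentions: Iterable[EntityMention], path) -> int:
    import json

    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": m.tweet_id,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "canonical": m.canonical,
                        "class": m.concept_class,
                    }
                )
                + "\n"
            )
            n += 1
    return n


def read_mentions(path) -> list:
    import json

    mentions = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            mentions.append(
                EntityMention(
                    tweet_id=obj["tweet_id"],
                    start=obj["start"],
                    end=obj["end"],
                    surface=obj["surface"],
                    canonical=obj["canonical"],
                    concept_class=obj["class"],
                )
            )
    return mentions
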