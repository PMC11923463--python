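"""Targeted sentiment scoring and time-series aggregation.

Any scorer receives the contract string ``"<tweet text> [SEP] <canonical>"``.
The baseline scorer is a deterministic valence-lexicon stand-in for an
external model adapter; aggregation is per-mention (a tweet naming two
drugs contributes to both), and the denominator of every ratio is the
mentions the scorer assigned one of the three classes.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .corpus_io import StudyWindow, TweetRecord, week_index
from .entities import EntityMention

logger = logging.getLogger(__name__)

SEP_TOKEN = "[SEP]"
POSITIVE = "positive"
NEUTRAL = "neutral"
NEGATIVE = "negative"
CLASSES = (POSITIVE, NEUTRAL, NEGATIVE)

#: matches the cue vocabulary emitted by the synthetic generator
DEFAULT_VALENCE_LEXICON = {
    "great": "+",
    "good": "+",
    "love": "+",
    "safe": "+",
    "effective": "+",
    "awful": "-",
    "bad": "-",
    "toxic": "-",
    "dangerous": "-",
    "useless": "-",
}

_TOKEN_RE = re.compile(r"[\w']+")


@dataclass(frozen=True)
class ScoredMention:
    mention: EntityMention
    sentiment: str
    scorer_id: str

    def __post_init__(self):
        if self.sentiment not in CLASSES:
            raise ValueError(f"sentiment must be one of {CLASSES}")


@dataclass
class WeeklySeries:
    """Ordered week-index -> value map; absent weeks are missing, not 0."""

    values: dict
    window: StudyWindow

    def __getitem__(self, week: int):
        return self.values[week]

    def get(self, week: int, default=None):
        return self.values.get(week, default)

    def items(self):
        return sorted(self.values.items())

    def total(self) -> float:
        return sum(self.values.values())

    def to_rows(self):
        """(week_start_date ISO, value) rows for CSV export."""
        return [
            (self.window.week_start(w).isoformat(), v) for w, v in self.items()
        ]


def scorer_input(record: TweetRecord, mention: EntityMention) -> str:
    """Build the exact string an external scorer adapter receives."""
    if mention.tweet_id != record.tweet_id:
        raise ValueError("mention does not belong to record")
    if not mention.canonical:
        raise ValueError("empty canonical concept")
    return f"{record.text} {SEP_TOKEN} {mention.canonical}"


def split_scorer_input(payload: str):
    """Recover (tweet text, entity) from a contract string."""
    idx = payload.rfind(f" {SEP_TOKEN} ")
    if idx < 0:
        raise ValueError("payload lacks [SEP] delimiter")
    return payload[:idx], payload[idx + len(SEP_TOKEN) + 2 :]


def baseline_scorer(
    payload: str,
    valence_lexicon: Optional[Mapping[str, str]] = None,
) -> str:
    """Cue-token counting over the tweet part: positive if positive cues
    outnumber negative cues, negative if the reverse, neutral on ties."""
    lexicon = valence_lexicon if valence_lexicon is not None else DEFAULT_VALENCE_LEXICON
    text, _entity = split_scorer_input(payload)
    pos = neg = 0
    for token in _TOKEN_RE.findall(text.lower()):
        val = lexicon.get(token)
        if val == "+":
            pos += 1
        elif val == "-":
            neg += 1
    if pos > neg:
        return POSITIVE
    if neg > pos:
        return NEGATIVE
    return NEUTRAL


def score_mentions(
    records: Iterable[TweetRecord],
    mentions: Iterable[EntityMention],
    scorer: Optional[Callable[[str], str]] = None,
    scorer_id: str = "baseline",
) -> list:
    """Score every mention; mentions the scorer raises on are skipped
    (abstention) and excluded from all denominators."""
    scorer = scorer or baseline_scorer
    by_id = {rec.tweet_id: rec for rec in records}
    scored = []
    n_abstained = 0
    for m in mentions:
        rec = by_id.get(m.tweet_id)
        if rec is None:
            n_abstained += 1
            continue
        try:
            label = scorer(scorer_input(rec, m))
        except Exception:  # adapter failure = abstention
            n_abstained += 1
            continue
        scored.append(ScoredMention(mention=m, sentiment=label, scorer_id=scorer_id))
    if n_abstained:
        logger.info("scorer abstained on %d mentions", n_abstained)
    return scored


def sentiment_distribution(scored: Sequence[ScoredMention]) -> dict:
    """Per-canonical (p_pos, p_neu, p_neg) over all scored mentions."""
    counts: dict = defaultdict(Counter)
    for s in scored:
        counts[s.mention.canonical][s.sentiment] += 1
    out = {}
    for canonical, c in counts.items():
        total = sum(c.values())
        if total == 0:
            logger.warning("no scored mentions for %s; omitted", canonical)
            continue
        out[canonical] = tuple(c.get(cls, 0) / total for cls in CLASSES)
    return out


def weekly_polarity_ratio(
    scored: Sequence[ScoredMention],
    timestamps: Mapping[str, datetime],
    canonical: str,
    polarity: str,
    window: StudyWindow,
) -> WeeklySeries:
    """Per-week fraction of a canonical's scored mentions with a polarity.

    Weeks with no scored mentions of the canonical are missing from the
    series rather than zero.
    """
    if polarity not in (POSITIVE, NEGATIVE):
        raise ValueError("polarity must be positive or negative")
    num: Counter = Counter()
    den: Counter = Counter()
    for s in scored:
        if s.mention.canonical != canonical:
            continue
        w = week_index(timestamps[s.mention.tweet_id], window)
        den[w] += 1
        if s.sentiment == polarity:
            num[w] += 1
    values = {w: num.get(w, 0) / d for w, d in den.items()}
    return WeeklySeries(values=values, window=window)


def mention_series(
    mentions: Sequence[EntityMention],
    timestamps: Mapping[str, datetime],
    canonical: str,
    window: StudyWindow,
) -> WeeklySeries:
    """Raw mention counts per week for one canonical."""
    counts: Counter = Counter()
    for m in mentions:
        if m.canonical != canonical:
            continue
        counts[week_index(timestamps[m.tweet_id], window)] += 1
    return WeeklySeries(values=dict(counts), window=window)


def top_k_concepts(
    counts: Mapping[str, int],
    k: int = 5,
    concept_class: Optional[str] = None,
    class_of: Optional[Mapping[str, str]] = None,
) -> list:
    """Top-k canonicals by count, ties broken lexicographically (logged)."""
    items = [
        (c, n)
        for c, n in counts.items()
        if concept_class is None
        or (class_of or {}).get(c) == concept_class
    ]
    items.sort(key=lambda cn: (-cn[1], cn[0]))
    if len(items) < k:
        logger.warning("only %d concepts available for top-%d", len(items), k)
    by_count = Counter(n for _, n in items[:k])
    if any(v > 1 for v in by_count.values()):
        logger.info("ties in top-%d broken lexicographically", k)
    return [c for c, _ in items[:k]]


def write_scored(scored: Iterable[ScoredMention], path) -> int:
    import json

    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for s in scored:
            m = s.mention
            fh.write(
                json.dumps(
                    {
                        "tweet_id": m.tweet_id,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "canonical": m.canonical,
                        "class": m.concept_class,
                        "sentiment": s.sentiment,
                        "scorer_id": s.scorer_id,
                    }
                )
                + "\n"
            )
            n += 1
    return n


def write_series(series: WeeklySeries, path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["week_start_date", "value"])
        for row in series.to_rows():
            writer.writerow(row)
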