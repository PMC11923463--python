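"""Corpus reading, validation, preprocessing, and weekly binning.

Corpora are line-delimited JSON (one object per line with keys ``tweet_id``,
``user_id``, ``created_at`` and ``text``) or CSV with the same columns.
Weekly binning uses consecutive 7-day bins anchored at the study-window
start, not ISO weeks.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

#: scheme-prefixed links or bare www.-prefixed tokens
URL_PATTERN = re.compile(r"https?://\S+|\bwww\.\S+", re.IGNORECASE)

_HANDLE_PATTERN = re.compile(r"@(\w+)")

DEFAULT_WINDOW_START = date(2020, 2, 1)
DEFAULT_WINDOW_END = date(2022, 4, 30)


class CorpusFormatError(ValueError):
    """Raised when a corpus file is unreadable or mostly malformed."""


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive calendar window with a week anchor for 7-day binning."""

    start_date: date = DEFAULT_WINDOW_START
    end_date: date = DEFAULT_WINDOW_END
    week_anchor: Optional[date] = None

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        anchor = self.week_anchor if self.week_anchor is not None else self.start_date
        if anchor > self.start_date:
            raise ValueError("week_anchor must be <= start_date")
        object.__setattr__(self, "week_anchor", anchor)

    @property
    def n_weeks(self) -> int:
        """Number of 7-day bins covering the window (last may be partial)."""
        return week_index(_at_utc(self.end_date), self) + 1

    def contains(self, ts: datetime) -> bool:
        d = ts.astimezone(timezone.utc).date()
        return self.start_date <= d <= self.end_date

    def week_start(self, index: int) -> date:
        return self.week_anchor + timedelta(days=7 * index)


@dataclass(frozen=True)
class TweetRecord:
    """One timestamped short text; the atomic unit of every stage."""

    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str


def _at_utc(d: date) -> datetime:
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc)


def week_index(timestamp: datetime, window: StudyWindow) -> int:
    """Anchor-aligned 7-day bin index of ``timestamp`` within ``window``."""
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    if not window.contains(timestamp):
        raise ValueError(f"timestamp {timestamp.isoformat()} outside study window")
    days = (timestamp.astimezone(timezone.utc).date() - window.week_anchor).days
    return days // 7


def parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _validate_row(row: dict, window: Optional[StudyWindow]) -> TweetRecord:
    for key in ("tweet_id", "user_id", "created_at", "text"):
        if key not in row or row[key] is None or str(row[key]) == "":
            raise ValueError(f"missing field {key!r}")
    text = str(row["text"])
    if not text.strip():
        raise ValueError("empty text")
    ts = parse_timestamp(row["created_at"])
    record = TweetRecord(
        tweet_id=str(row["tweet_id"]),
        user_id=str(row["user_id"]),
        timestamp=ts,
        text=text,
    )
    if window is not None and not window.contains(ts):
        raise ValueError("timestamp outside study window")
    return record


@dataclass
class CorpusReadResult:
    records: list
    n_skipped: int = 0
    n_duplicates: int = 0

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _iter_rows(path: Path, fmt: str) -> Iterator[dict]:
    if fmt == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    obj = {"__malformed__": True}
                yield obj if isinstance(obj, dict) else {"__malformed__": True}
    elif fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                yield row
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def read_corpus(
    path,
    fmt: str = "jsonl",
    window: Optional[StudyWindow] = None,
) -> CorpusReadResult:
    """Read and validate a corpus file.

    Malformed records (missing fields, unparsable timestamps, out-of-window
    timestamps when ``window`` is given) are counted and skipped; duplicate
    ``tweet_id`` values keep the first occurrence. More than 50% malformed
    records in a non-empty file is a fatal format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[TweetRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    n_dup = 0
    n_total = 0
    for row in _iter_rows(path, fmt):
        n_total += 1
        try:
            if "__malformed__" in row:
                raise ValueError("unparsable line")
            rec = _validate_row(row, window)
        except (ValueError, TypeError) as exc:
            logger.debug("skipping malformed record %d: %s", n_total, exc)
            n_skipped += 1
            continue
        if rec.tweet_id in seen:
            logger.warning("duplicate tweet_id %s; keeping first", rec.tweet_id)
            n_dup += 1
            continue
        seen.add(rec.tweet_id)
        records.append(rec)
    if n_total > 0 and n_skipped > n_total / 2:
        raise CorpusFormatError(
            f"{n_skipped}/{n_total} records malformed in {path}"
        )
    if n_skipped:
        logger.info("read %d records, skipped %d malformed", len(records), n_skipped)
    return CorpusReadResult(records=records, n_skipped=n_skipped, n_duplicates=n_dup)


def write_corpus(records: Iterable[TweetRecord], path, fmt: str = "jsonl") -> int:
    """Write records; inverse of :func:`read_corpus` on valid input."""
    path = Path(path)
    n = 0
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(
                    json.dumps(
                        {
                            "tweet_id": rec.tweet_id,
                            "user_id": rec.user_id,
                            "created_at": rec.timestamp.astimezone(timezone.utc)
                            .isoformat()
                            .replace("+00:00", "Z"),
                            "text": rec.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
                n += 1
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tweet_id", "user_id", "created_at", "text"])
            for rec in records:
                writer.writerow(
                    [
                        rec.tweet_id,
                        rec.user_id,
                        rec.timestamp.astimezone(timezone.utc)
                        .isoformat()
                        .replace("+00:00", "Z"),
                        rec.text,
                    ]
                )
                n += 1
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return n


def contains_url(text: str) -> bool:
    return URL_PATTERN.search(text) is not None


def filter_urls(
    records: Iterable[TweetRecord],
    pattern: re.Pattern = URL_PATTERN,
) -> tuple[list, int]:
    """Drop records whose text contains a hyperlink.

    Returns ``(kept, n_removed)``; kept and removed partition the input.
    """
    kept = []
    n_removed = 0
    for rec in records:
        if pattern.search(rec.text):
            n_removed += 1
        else:
            kept.append(rec)
    return kept, n_removed


def mask_users(text: str, allowlist: Optional[Iterable[str]] = None) -> str:
    """Replace every ``@handle`` not in the allowlist with ``@USER``.

    Allowlisted handles (public figures) are preserved verbatim; matching
    against the allowlist is case-insensitive.
    """
    allowed = {h.lstrip("@").lower() for h in (allowlist or ())}

    def _sub(match: re.Match) -> str:
        handle = match.group(1)
        return match.group(0) if handle.lower() in allowed else "@USER"

    return _HANDLE_PATTERN.sub(_sub, text)
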