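"""Ingestion of tweet-like records: reading, keyword filtering, tokenization,
and aggregation to daily count series.

The unit of input is a :class:`TweetRecord` — one timestamped short text with
an original-vs-retweet flag.  Records arrive as JSONL (one object per line)
or CSV (RFC 4180 with a header row); column names are resolved through a
configurable field map whose defaults cover the common crawler exports
(``tweet``/``text``, ``date``/``created_at``, ``retweets_count``...).

Text cleaning is deliberately language-agnostic: URLs, @-mentions, retweet
markers and emoji are stripped, tokens are reduced to their letters, and a
caller-supplied stopword list is applied.  Morphological analysis for
agglutinative languages is out of scope; callers who need it can pre-tokenize
and feed whitespace-separated tokens.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "TokenizerSpec",
    "DailySeries",
    "IngestLog",
    "read_tweets",
    "filter_by_keywords",
    "preprocess_text",
    "build_daily_series",
]


@dataclass(frozen=True)
class TweetRecord:
    """One timestamped short-text record.

    ``is_retweet`` distinguishes the numerator (retweets) from the
    denominator (originals) of the tweet-depth statistic.  ``timestamp`` is a
    timezone-aware or naive :class:`pandas.Timestamp`; naive values are
    treated as UTC when binned to calendar days.
    """

    id: str
    timestamp: pd.Timestamp
    text: str
    user_id: str
    is_retweet: bool
    retweet_count: int = 0
    country_tag: str = ""

    def __post_init__(self) -> None:
        if self.retweet_count < 0:
            raise ValueError("retweet_count must be non-negative")


@dataclass
class IngestLog:
    """Bookkeeping for rows dropped during ingestion."""

    read: int = 0
    skipped_malformed: int = 0
    skipped_empty_text: int = 0
    skipped_duplicate_id: int = 0

    @property
    def kept(self) -> int:
        return (
            self.read
            - self.skipped_malformed
            - self.skipped_empty_text
            - self.skipped_duplicate_id
        )


# Default aliases, Twint-style names first.
_DEFAULT_FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id", "tweet_id", "status_id"),
    "timestamp": ("date", "created_at", "timestamp", "datetime"),
    "text": ("tweet", "text", "full_text"),
    "user_id": ("user_id", "username", "screen_name", "user"),
    "is_retweet": ("retweet", "is_retweet"),
    "retweet_count": ("retweets_count", "retweet_count", "nretweets"),
    "country_tag": ("country_tag", "country", "stream"),
}

_TRUTHY = {"true", "1", "yes", "t", "y"}


def _resolve(row: Mapping[str, object], aliases: tuple[str, ...]):
    for name in aliases:
        if name in row and row[name] is not None:
            return row[name]
    return None


def _coerce_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def _row_to_record(
    row: Mapping[str, object],
    aliases: Mapping[str, tuple[str, ...]],
    row_number: int,
) -> TweetRecord | None:
    """Build a record from one parsed row; None marks a malformed row."""
    raw_text = _resolve(row, aliases["text"])
    raw_ts = _resolve(row, aliases["timestamp"])
    if raw_text is None or raw_ts is None:
        return None
    text = str(raw_text)
    try:
        ts = pd.Timestamp(raw_ts)
    except (ValueError, TypeError):
        return None
    if pd.isna(ts):
        return None
    raw_id = _resolve(row, aliases["id"])
    rec_id = str(raw_id) if raw_id is not None else f"row{row_number}"
    raw_user = _resolve(row, aliases["user_id"])
    user_id = str(raw_user) if raw_user is not None else ""
    raw_rt = _resolve(row, aliases["is_retweet"])
    if raw_rt is not None:
        is_retweet = _coerce_bool(raw_rt)
    else:
        # Fallback when no flag column exists: a leading "RT @" marker.
        is_retweet = text.startswith("RT @")
    raw_count = _resolve(row, aliases["retweet_count"])
    try:
        retweet_count = int(float(raw_count)) if raw_count not in (None, "") else 0
    except (ValueError, TypeError):
        retweet_count = 0
    raw_tag = _resolve(row, aliases["country_tag"])
    return TweetRecord(
        id=rec_id,
        timestamp=ts,
        text=text,
        user_id=user_id,
        is_retweet=is_retweet,
        retweet_count=max(retweet_count, 0),
        country_tag=str(raw_tag) if raw_tag is not None else "",
    )


def _iter_rows(path: Path, format: str) -> Iterable[Mapping[str, object]]:
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    yield {"__malformed__": True}
                    continue
                if not isinstance(obj, dict):
                    yield {"__malformed__": True}
                    continue
                yield obj
    elif format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                yield {k: v for k, v in row.items() if k is not None}
    else:  # pragma: no cover - guarded in read_tweets
        raise ValueError(format)


def read_tweets(
    path: str | Path,
    format: str = "jsonl",
    field_map: Mapping[str, str] | None = None,
    log: IngestLog | None = None,
) -> list[TweetRecord]:
    """Read tweet records from a JSONL or CSV file.

    Parameters
    ----------
    path
        Input file, UTF-8.
    format
        ``"jsonl"`` (one JSON object per line) or ``"csv"`` (RFC 4180,
        header row).
    field_map
        Optional ``canonical_name -> column_name`` overrides; unspecified
        fields fall back to the built-in alias lists.
    log
        Optional :class:`IngestLog` that accumulates drop counts.

    Malformed rows (unparseable, or missing text/timestamp) are skipped and
    counted; records whose text is empty are dropped; duplicate ids keep the
    first occurrence.
    """
    path = Path(path)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}: expected 'jsonl' or 'csv'")
    if not path.exists():
        raise FileNotFoundError(path)
    if log is None:
        log = IngestLog()
    aliases = dict(_DEFAULT_FIELD_ALIASES)
    if field_map:
        for key, col in field_map.items():
            if key not in aliases:
                raise ValueError(f"unknown field-map key {key!r}")
            aliases[key] = (col,)

    records: list[TweetRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(_iter_rows(path, format)):
        log.read += 1
        if "__malformed__" in row:
            log.skipped_malformed += 1
            continue
        rec = _row_to_record(row, aliases, i)
        if rec is None:
            log.skipped_malformed += 1
            continue
        if not rec.text.strip():
            log.skipped_empty_text += 1
            continue
        if rec.id in seen_ids:
            log.skipped_duplicate_id += 1
            continue
        seen_ids.add(rec.id)
        records.append(rec)
    dropped = log.read - len(records)
    if dropped:
        logger.info(
            "read %d rows from %s: kept %d, skipped %d "
            "(malformed %d, empty text %d, duplicate id %d)",
            log.read, path, len(records), dropped,
            log.skipped_malformed, log.skipped_empty_text,
            log.skipped_duplicate_id,
        )
    return records


def filter_by_keywords(
    records: Sequence[TweetRecord], keywords: Iterable[str]
) -> list[TweetRecord]:
    """Retain records whose text contains any collection keyword.

    Matching is case-insensitive substring matching, so off-topic uses of a
    keyword are retained by design (mirroring keyword-based crawling, which
    cannot distinguish senses).  A leading ``#`` on a keyword is ignored:
    hashtag keywords match both hashtagged and plain occurrences.
    """
    kws = {k.lstrip("#").casefold() for k in keywords if k.lstrip("#")}
    if not kws:
        raise ValueError("keyword set must be non-empty")
    out = []
    for rec in records:
        text = rec.text.casefold()
        if any(kw in text for kw in kws):
            out.append(rec)
    return out


_URL_RE = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_RT_RE = re.compile(r"^\s*RT\b[: ]?", re.IGNORECASE)

_DEFAULT_RULES = ("urls", "mentions", "rt_marker", "lowercase", "letters_only")


@dataclass(frozen=True)
class TokenizerSpec:
    """Language-specific cleaning configuration.

    ``rules`` is an ordered subset of ``{"urls", "mentions", "rt_marker",
    "lowercase", "letters_only"}``; stopwords are removed after all rules.
    Applying the spec to its own output is a no-op (idempotence), which the
    property suite checks by re-tokenizing the joined token stream.
    """

    language: str = "und"
    stopwords: frozenset[str] = field(default_factory=frozenset)
    rules: tuple[str, ...] = _DEFAULT_RULES

    def __post_init__(self) -> None:
        unknown = set(self.rules) - set(_DEFAULT_RULES)
        if unknown:
            raise ValueError(f"unknown cleaning rules: {sorted(unknown)}")
        object.__setattr__(self, "stopwords", frozenset(
            s.casefold() for s in self.stopwords
        ))


def _letters_only(token: str) -> str:
    # Keep unicode letters (category L*); drops digits, punctuation, emoji.
    return "".join(ch for ch in token if unicodedata.category(ch).startswith("L"))


def preprocess_text(text: str, spec: TokenizerSpec | None = None) -> list[str]:
    """Clean and tokenize one text into meaningful units.

    Removes URLs, mentions, retweet markers, emoji/non-letter characters and
    stopwords according to ``spec``; surviving tokens keep their original
    order.  Whitespace is the token boundary.
    """
    if spec is None:
        spec = TokenizerSpec()
    if "urls" in spec.rules:
        text = _URL_RE.sub(" ", text)
    if "rt_marker" in spec.rules:
        text = _RT_RE.sub(" ", text)
    if "mentions" in spec.rules:
        text = _MENTION_RE.sub(" ", text)
    tokens = []
    for raw in text.split():
        tok = raw
        if "letters_only" in spec.rules:
            tok = _letters_only(tok)
        if "lowercase" in spec.rules:
            tok = tok.casefold()
        if not tok:
            continue
        if tok.casefold() in spec.stopwords:
            continue
        tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class DailySeries:
    """Per-calendar-day counts over a contiguous date range.

    ``counts[t]`` is the number of records whose local date is
    ``start_date + t`` days; days without tweets carry 0.
    """

    start_date: date
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=float)
        )
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end_date(self) -> date:
        return self.start_date + timedelta(days=len(self.counts) - 1)

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(len(self))]

    def date_of(self, index: int) -> date:
        return self.start_date + timedelta(days=int(index))

    def index_of(self, day: date) -> int:
        idx = (day - self.start_date).days
        if not 0 <= idx < len(self):
            raise KeyError(f"{day} outside series range")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates(), "count": self.counts})


def local_date(ts: pd.Timestamp, timezone: str = "UTC") -> date:
    """Calendar date of a timestamp in the given zone (naive == UTC)."""
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert(timezone).date()


def build_daily_series(
    records: Sequence[TweetRecord],
    window: tuple[date, date],
    timezone: str = "UTC",
) -> DailySeries:
    """Aggregate records to a daily count series over ``window`` (inclusive).

    Records falling outside the window are excluded and their count logged.
    The sum of the returned counts equals the number of in-window records.
    """
    start, end = window
    if end < start:
        raise ValueError("window end before start")
    n_days = (end - start).days + 1
    counts = np.zeros(n_days)
    outside = 0
    for rec in records:
        day = local_date(rec.timestamp, timezone)
        offset = (day - start).days
        if 0 <= offset < n_days:
            counts[offset] += 1
        else:
            outside += 1
    if outside:
        logger.info("excluded %d records outside window %s..%s", outside, start, end)
    return DailySeries(start_date=start, counts=counts)
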