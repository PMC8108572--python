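"""Phase-level descriptive statistics, country-mention series and diversity.

Per phase this module reports the summary statistics a risk-communication
study tabulates: total tweets, average distinct users per day, average
original tweets and retweets per day, and *tweet depth* — the ratio of
average retweets per day to average original tweets per day, a standardized
cascade-depth measure (higher means each original spreads further).
Reported ratios are rounded half-up to two decimals.

It also counts per-day tweets mentioning other countries' names (binary per
tweet per country, any listed name variant) and computes per-day topic
diversity from a theme weight table: the number of active themes and the
Shannon entropy of the theme mixture normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import TweetRecord, local_date
from .phase_detect import PhaseSegmentation

__all__ = [
    "PhaseStats",
    "tweet_depth",
    "phase_stats",
    "country_mentions",
    "topic_diversity",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matching tabulated reporting)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhaseStats:
    """Tabulated per-phase summary of communication volume and depth."""

    phase_id: int
    start: date
    end: date
    n_days: int
    total_tweets: int
    avg_users_per_day: float
    avg_original_per_day: float
    avg_retweets_per_day: float
    tweet_depth: float
    n_topics_perplexity: int | None = None
    n_major_topics: int | None = None
    n_final_topics: int | None = None


def tweet_depth(avg_retweets_per_day: float, avg_original_per_day: float) -> float:
    """Retweets per day divided by original tweets per day, rounded to 2 dp.

    Returns 0.0 when there are no originals (no cascade to measure).
    """
    if avg_retweets_per_day < 0 or avg_original_per_day < 0:
        raise ValueError("per-day averages must be non-negative")
    if avg_original_per_day == 0:
        return 0.0
    return round2(avg_retweets_per_day / avg_original_per_day)


def phase_stats(
    records: Sequence[TweetRecord],
    segmentation: PhaseSegmentation,
    topics_meta: Mapping[int, Mapping[str, int]] | None = None,
    timezone: str = "UTC",
) -> list[PhaseStats]:
    """Per-phase volume statistics from the raw records.

    Averages divide phase totals by the number of calendar days in the phase
    (both ends inclusive); users are counted as distinct user ids per day,
    then averaged over days.  ``topics_meta`` optionally supplies, per
    phase id, ``n_topics_perplexity`` / ``n_major_topics`` /
    ``n_final_topics`` from the modeling and labeling stages.
    """
    per_phase_days: dict[int, dict[date, set[str]]] = {
        ph.phase_id: {} for ph in segmentation
    }
    originals: dict[int, int] = {ph.phase_id: 0 for ph in segmentation}
    retweets: dict[int, int] = {ph.phase_id: 0 for ph in segmentation}
    totals: dict[int, int] = {ph.phase_id: 0 for ph in segmentation}

    for rec in records:
        day = local_date(rec.timestamp, timezone)
        ph = segmentation.phase_of(day)
        totals[ph.phase_id] += 1
        if rec.is_retweet:
            retweets[ph.phase_id] += 1
        else:
            originals[ph.phase_id] += 1
        per_phase_days[ph.phase_id].setdefault(day, set()).add(rec.user_id)

    out = []
    for ph in segmentation:
        n_days = ph.n_days
        users_by_day = per_phase_days[ph.phase_id]
        avg_users = sum(len(u) for u in users_by_day.values()) / n_days
        avg_orig = originals[ph.phase_id] / n_days
        avg_rt = retweets[ph.phase_id] / n_days
        meta = (topics_meta or {}).get(ph.phase_id, {})
        out.append(
            PhaseStats(
                phase_id=ph.phase_id,
                start=ph.start,
                end=ph.end,
                n_days=n_days,
                total_tweets=totals[ph.phase_id],
                avg_users_per_day=avg_users,
                avg_original_per_day=avg_orig,
                avg_retweets_per_day=avg_rt,
                tweet_depth=tweet_depth(avg_rt, avg_orig),
                n_topics_perplexity=meta.get("n_topics_perplexity"),
                n_major_topics=meta.get("n_major_topics"),
                n_final_topics=meta.get("n_final_topics"),
            )
        )
    return out


def phase_stats_frame(stats: Sequence[PhaseStats]) -> pd.DataFrame:
    """Phase statistics as a table (one row per phase)."""
    return pd.DataFrame([s.__dict__ for s in stats]).set_index("phase_id")


def country_mentions(
    records: Sequence[TweetRecord],
    name_dict: Mapping[str, Iterable[str]],
    timezone: str = "UTC",
) -> pd.DataFrame:
    """Daily counts of tweets mentioning each country.

    ``name_dict`` maps a country key to its name variants (local language or
    English); matching is case-insensitive substring, and a tweet counts at
    most once per country no matter how many variants or repeats it
    contains.  Returns a date x country table.
    """
    if not name_dict:
        raise ValueError("name_dict must be non-empty")
    variants = {
        country: [v.casefold() for v in names] for country, names in name_dict.items()
    }
    cells: dict[tuple[date, str], int] = {}
    for rec in records:
        text = rec.text.casefold()
        day = local_date(rec.timestamp, timezone)
        for country, names in variants.items():
            if any(v in text for v in names):
                cells[(day, country)] = cells.get((day, country), 0) + 1
    if not cells:
        return pd.DataFrame(columns=list(name_dict))
    df = pd.Series(cells).unstack(fill_value=0)
    df.index.name = "date"
    for country in name_dict:
        if country not in df.columns:
            df[country] = 0
    return df[list(name_dict)].sort_index()


def topic_diversity(theme_weights: pd.DataFrame) -> pd.DataFrame:
    """Per-day topic diversity of a daily theme weight table.

    For each day: ``n_active`` — themes with positive weight — and
    ``entropy`` — the Shannon entropy of the day's theme mixture divided by
    log of the number of themes in the table, so a uniform spread over all
    themes scores 1 and a single active theme scores 0.  Days with zero
    total weight are emitted as missing.
    """
    if theme_weights.empty:
        return pd.DataFrame(columns=["n_active", "entropy"])
    k = theme_weights.shape[1]
    rows = []
    for day, row in theme_weights.iterrows():
        total = row.sum()
        if total <= 0:
            rows.append((day, np.nan, np.nan))
            continue
        p = row[row > 0].to_numpy() / total
        h = float(-(p * np.log(p)).sum())
        entropy = h / np.log(k) if k > 1 else 0.0
        rows.append((day, int((row > 0).sum()), entropy))
    out = pd.DataFrame(rows, columns=["date", "n_active", "entropy"])
    return out.set_index("date")
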