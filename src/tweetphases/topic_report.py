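"""Topic ranking, annotation bundles, theme labeling and agreement scoring.

After LDA assigns each tweet a dominant topic, topics are ranked by tweet
count and the minor tail is discarded: the retained "major topics" are the
minimal descending-prevalence prefix covering at least 75% of the phase's
tweets.  For human labeling, each major topic is exported as the up-to-1000
most-retweeted tweets plus its 30 highest-probability keywords.  Annotators
assign each topic one or two theme labels (two at most); in daily trend
tables a dual-labeled topic contributes weight 0.5 per tweet to each theme,
so per-day theme weights always sum to the labeled tweet count.  Intercoder
reliability is scored with Cohen's kappa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import TweetRecord, local_date

__all__ = [
    "TopicSummary",
    "ThemeLabelMap",
    "rank_and_filter_topics",
    "annotation_bundle",
    "apply_theme_labels",
    "cohen_kappa",
]

MAJOR_TOPIC_MASS = 0.75  # retained prefix covers >= this share of tweets
TOP_RETWEETED = 1000
TOP_WORDS = 30


@dataclass(frozen=True)
class TopicSummary:
    """Prevalence and annotation material for one topic."""

    topic_id: int
    tweet_count: int
    share: float
    top_words: tuple[tuple[str, float], ...] = ()
    top_retweeted: tuple[str, ...] = ()


@dataclass(frozen=True)
class ThemeLabelMap:
    """Editable topic -> theme(s) map produced by human annotators.

    Each topic carries one or two theme labels; themes may carry sublabels
    (e.g. ``news_confirmed``, ``outbreak_hate``) that are treated as opaque
    theme names here.  Merging of similar topics is expressed by mapping
    several topic ids to the same theme.
    """

    labels: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for topic_id, themes in self.labels.items():
            themes = tuple(themes)
            if not 1 <= len(themes) <= 2:
                raise ValueError(
                    f"topic {topic_id} has {len(themes)} labels; "
                    "each topic takes 1 or 2"
                )
            norm[int(topic_id)] = themes
        object.__setattr__(self, "labels", norm)

    def themes_for(self, topic_id: int | None) -> tuple[str, ...]:
        if topic_id is None:
            return ("unlabeled",)
        return self.labels.get(topic_id, ("unlabeled",))

    @classmethod
    def from_json_obj(cls, obj: Mapping[str, Sequence[str]]) -> "ThemeLabelMap":
        return cls(labels={int(k): tuple(v) for k, v in obj.items()})


def rank_and_filter_topics(
    assignments: Mapping[str, int | None],
    model=None,
    records: Mapping[str, TweetRecord] | None = None,
    rule: str = "cumulative",
    vocab=None,
) -> list[TopicSummary]:
    """Rank topics by tweet count and discard the minor tail.

    Under the default ``"cumulative"`` rule the retained set is the minimal
    descending-count prefix whose cumulative share reaches at least 75% of
    assigned tweets (the discarded tail holds under 25% plus any boundary
    mass).  ``rule="per_topic"`` instead keeps every topic whose own share
    is at least 25%.  Count ties break toward the lower topic id.

    When ``model`` (an :class:`~tweetphases.topic_model.LdaTopicModel`) and
    ``vocab`` are given, each summary carries the topic's 30 most probable
    words; when ``records`` is given, the up-to-1000 most-retweeted record
    ids (ties: earlier timestamp first).
    """
    labeled = {rid: t for rid, t in assignments.items() if t is not None}
    if not labeled:
        raise ValueError("no assigned topics")
    counts = Counter(labeled.values())
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    if rule == "cumulative":
        retained_ids = []
        cum = 0
        for topic_id, c in ordered:
            retained_ids.append(topic_id)
            cum += c
            if cum / total >= MAJOR_TOPIC_MASS:
                break
    elif rule == "per_topic":
        retained_ids = [t for t, c in ordered if c / total >= 0.25]
    else:
        raise ValueError(f"unknown filter rule {rule!r}")

    by_topic: dict[int, list[str]] = {t: [] for t in retained_ids}
    for rid, t in labeled.items():
        if t in by_topic:
            by_topic[t].append(rid)

    summaries = []
    for topic_id in retained_ids:
        top_words: tuple[tuple[str, float], ...] = ()
        if model is not None and vocab is not None:
            row = model.topic_word[topic_id]
            idx = np.argsort(-row)[:TOP_WORDS]
            id2tok = vocab.id_to_token
            top_words = tuple((id2tok[i], float(row[i])) for i in idx)
        top_retweeted: tuple[str, ...] = ()
        if records is not None:
            members = [records[rid] for rid in by_topic[topic_id] if rid in records]
            members.sort(key=lambda r: (-r.retweet_count, r.timestamp, r.id))
            top_retweeted = tuple(r.id for r in members[:TOP_RETWEETED])
        summaries.append(
            TopicSummary(
                topic_id=topic_id,
                tweet_count=counts[topic_id],
                share=counts[topic_id] / total,
                top_words=top_words,
                top_retweeted=top_retweeted,
            )
        )
    return summaries


def annotation_bundle(
    topics: Sequence[TopicSummary],
    records: Mapping[str, TweetRecord],
    out_dir: str | Path,
) -> list[Path]:
    """Write per-topic annotation files for human labelers.

    For each topic: ``topic_<id>_tweets.tsv`` with the most-retweeted tweets
    (id, retweet count, date, text) and ``topic_<id>_words.tsv`` with the top
    keywords and probabilities.  Output is deterministic; topics with fewer
    than 1000 retweeted tweets list all of them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for summary in topics:
        tweets_path = out_dir / f"topic_{summary.topic_id}_tweets.tsv"
        with tweets_path.open("w", encoding="utf-8") as fh:
            fh.write("record_id\tretweet_count\tdate\ttext\n")
            for rid in summary.top_retweeted:
                rec = records[rid]
                text = rec.text.replace("\t", " ").replace("\n", " ")
                fh.write(
                    f"{rec.id}\t{rec.retweet_count}\t"
                    f"{local_date(rec.timestamp)}\t{text}\n"
                )
        words_path = out_dir / f"topic_{summary.topic_id}_words.tsv"
        with words_path.open("w", encoding="utf-8") as fh:
            fh.write("token\tprobability\n")
            for tok, p in summary.top_words[:TOP_WORDS]:
                fh.write(f"{tok}\t{p:.6g}\n")
        written += [tweets_path, words_path]
    return written


def apply_theme_labels(
    assignments: Mapping[str, int | None],
    label_map: ThemeLabelMap,
    records: Mapping[str, TweetRecord],
    timezone: str = "UTC",
) -> pd.DataFrame:
    """Daily theme weight table from per-tweet topic assignments.

    Each tweet contributes total weight 1 to its day: the full unit to its
    topic's single theme, or 0.5 to each of a dual-labeled topic's themes.
    Rows are calendar days, columns themes; per-day row sums equal the
    labeled tweet counts exactly.
    """
    cells: Counter[tuple[object, str]] = Counter()
    for rid, topic_id in assignments.items():
        if topic_id is None:
            continue
        rec = records[rid]
        day = local_date(rec.timestamp, timezone)
        themes = label_map.themes_for(topic_id)
        w = 1.0 / len(themes)
        for theme in themes:
            cells[(day, theme)] += w
    if not cells:
        return pd.DataFrame()
    df = pd.Series(cells).unstack(fill_value=0.0)
    df.index.name = "date"
    return df.sort_index()


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa for intercoder agreement between two annotators.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    marginal label frequencies.  When both annotators use a single identical
    label throughout (p_e = 1 with perfect agreement) kappa is 1 by
    convention.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("need at least 2 items")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    freq_a = Counter(labels_a)
    freq_b = Counter(labels_b)
    p_e = sum(freq_a[c] * freq_b.get(c, 0) for c in freq_a) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
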