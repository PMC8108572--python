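"""Synthetic tweet-stream generator with known ground truth.

Every pipeline stage — ingestion, phase detection, topic modeling, theme
trends — needs inputs whose correct answer is known.  This module generates
seeded streams with:

* a daily volume curve: a constant baseline rate modulated by surge events
  (log-linear rise to a peak multiplier, then log-linear decay back to
  baseline), with Poisson-distributed daily counts around the curve;
* a finite synthetic vocabulary (``tok0001``...) and ``k_true`` topic-word
  distributions drawn from a sparse Dirichlet, so topics are well separated;
* per-phase topic mixtures (phases delimited by the surge onsets), each
  document drawing one topic and then its tokens i.i.d. from that topic;
* optional volume-coupled topic concentration: on higher-volume days the
  daily topic mixture is drawn from a smaller Dirichlet parameter, making
  busy days topically *less* diverse — the generative analogue of the
  inverse volume-diversity relationship;
* retweets with phase-dependent rates, each referencing an earlier original
  of the stream and copying its text;
* country-name mentions injected with per-country probabilities.

The returned truth bundle records surge onsets, the daily rate curve and
realized counts, the topic-word matrix and each document's topic, so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import TweetRecord
from .topic_model import align_topics

__all__ = [
    "SurgeEvent",
    "GeneratorConfig",
    "generate_stream",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SurgeEvent:
    """One attention surge: log-linear rise to a peak, then decay.

    The rate multiplier is 1 before ``onset``; on day ``onset + k``
    (k = 0..rise_days-1) it is ``peak_multiplier ** ((k+1)/rise_days)``,
    reaching the peak on day ``onset + rise_days - 1``; it then declines
    log-linearly back to 1 over ``decay_days`` days.
    """

    onset: date
    peak_multiplier: float = 8.0
    rise_days: int = 3
    decay_days: int = 10

    def __post_init__(self) -> None:
        if self.peak_multiplier <= 1:
            raise ValueError("peak_multiplier must exceed 1")
        if self.rise_days < 1 or self.decay_days < 1:
            raise ValueError("rise_days and decay_days must be positive")

    def multiplier(self, day: date) -> float:
        k = (day - self.onset).days
        if k < 0:
            return 1.0
        if k < self.rise_days:
            return self.peak_multiplier ** ((k + 1) / self.rise_days)
        j = k - (self.rise_days - 1)  # days past the peak
        if j <= self.decay_days:
            return self.peak_multiplier ** (1 - j / self.decay_days)
        return 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic stream.

    Defaults describe a stream in which each surge onset day satisfies the
    velocity/acceleration detection condition after smoothing: a baseline of
    100 tweets/day with pronounced, fast-rising surges (peak 8x over 3 days)
    whose onset-day derivatives dominate the Poisson noise.  The ground-truth
    announcement (:attr:`gt_date`) falls one day into the first surge, where
    velocity is already high but acceleration is past its peak — so a later
    surge's onset day shows acceleration above, and velocity below, the
    anchored thresholds.
    """

    window: tuple[date, date]
    baseline_rate: float = 100.0
    surges: tuple[SurgeEvent, ...] = ()
    announcement_lag_days: int = 1
    vocab_size: int = 200
    k_true: int = 3
    topic_word_concentration: float = 0.05
    doc_topic_concentration: float = 5.0
    tokens_per_doc_mean: float = 12.0
    retweet_prob: tuple[float, ...] = (0.3,)
    mention_prob: Mapping[str, float] = field(default_factory=dict)
    volume_entropy_coupling: float = 0.0
    n_users: int = 200
    country_tag: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = self.window
        if end < start:
            raise ValueError("window: end before start")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for s in self.surges:
            if not start <= s.onset <= end:
                raise ValueError(f"surge onset {s.onset} outside window")
        if not 2 <= self.k_true <= self.vocab_size:
            raise ValueError("k_true must be in [2, vocab_size]")
        for p in self.retweet_prob:
            if not 0 <= p <= 1:
                raise ValueError("retweet_prob entries must lie in [0, 1]")
        for c, p in self.mention_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"mention_prob[{c}] must lie in [0, 1]")
        if self.tokens_per_doc_mean <= 0:
            raise ValueError("tokens_per_doc_mean must be positive")
        object.__setattr__(self, "surges", tuple(self.surges))
        object.__setattr__(self, "retweet_prob", tuple(self.retweet_prob))

    @property
    def n_days(self) -> int:
        start, end = self.window
        return (end - start).days + 1

    @property
    def gt_date(self) -> date | None:
        """Date of the stream's simulated first-case announcement.

        Public chatter starts rising before the official announcement (the
        rumor phase), so the announcement lands ``announcement_lag_days``
        into the first surge; its velocity/acceleration signature there is
        what the detector's thresholds are calibrated on.
        """
        if not self.surges:
            return None
        return self.surges[0].onset + timedelta(days=self.announcement_lag_days)

    def phase_of(self, day: date) -> int:
        """Phase index delimited by surge onsets (0 before the first)."""
        return sum(1 for s in self.surges if s.onset <= day)

    def rate_on(self, day: date) -> float:
        m = 1.0
        for s in self.surges:
            m *= s.multiplier(day)
        return self.baseline_rate * m


def generate_stream(
    config: GeneratorConfig,
) -> tuple[list[TweetRecord], dict]:
    """Generate one synthetic stream and its ground truth.

    Returns the records (chronological) and a truth dict with keys
    ``phase_onsets``, ``rates``, ``daily_counts``, ``topic_word``,
    ``doc_topic`` (record id -> true topic), ``vocabulary`` and
    ``daily_topic_mixture``.
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.window
    days = [start + timedelta(days=i) for i in range(config.n_days)]
    vocab = [f"tok{i:04d}" for i in range(config.vocab_size)]

    topic_word = rng.dirichlet(
        np.full(config.vocab_size, config.topic_word_concentration),
        size=config.k_true,
    )

    n_phases = len(config.surges) + 1
    phase_mixture = rng.dirichlet(
        np.full(config.k_true, config.doc_topic_concentration), size=n_phases
    )

    rates = np.array([config.rate_on(d) for d in days])
    daily_counts = rng.poisson(rates)

    user_pool = [f"user{i:04d}" for i in range(config.n_users)]
    countries = list(config.mention_prob)

    records: list[TweetRecord] = []
    originals: list[int] = []  # indices into records
    retweet_counts: dict[int, int] = {}
    doc_topic_truth: dict[str, int] = {}
    daily_mixture = np.zeros((config.n_days, config.k_true))
    rec_no = 0

    for di, (day, n_today) in enumerate(zip(days, daily_counts)):
        phase = config.phase_of(day)
        if config.volume_entropy_coupling > 0:
            # Busier days draw from a smaller Dirichlet parameter, so their
            # topic mixture concentrates on fewer topics.
            rel = max(rates[di] / config.baseline_rate, 1e-9)
            alpha = config.doc_topic_concentration * rel ** (
                -config.volume_entropy_coupling
            )
            mixture = rng.dirichlet(np.full(config.k_true, max(alpha, 1e-4)))
        else:
            mixture = phase_mixture[phase]
        daily_mixture[di] = mixture
        rt_p = config.retweet_prob[min(phase, len(config.retweet_prob) - 1)]
        hours = np.sort(rng.uniform(0, 24, size=n_today))
        for h in hours:
            rec_id = f"syn{rec_no:07d}"
            rec_no += 1
            ts = pd.Timestamp(day) + pd.Timedelta(hours=float(h))
            user = user_pool[rng.integers(len(user_pool))]
            is_retweet = bool(rng.random() < rt_p) and bool(originals)
            if is_retweet:
                src_idx = originals[rng.integers(len(originals))]
                src = records[src_idx]
                text = src.text
                topic = doc_topic_truth[src.id]
                retweet_counts[src_idx] = retweet_counts.get(src_idx, 0) + 1
            else:
                topic = int(rng.choice(config.k_true, p=mixture))
                n_tok = max(1, int(rng.poisson(config.tokens_per_doc_mean)))
                token_ids = rng.choice(
                    config.vocab_size, size=n_tok, p=topic_word[topic]
                )
                words = [vocab[t] for t in token_ids]
                for c in countries:
                    if rng.random() < config.mention_prob[c]:
                        words.append(c)
                text = " ".join(words)
            doc_topic_truth[rec_id] = topic
            if not is_retweet:
                originals.append(len(records))
            records.append(
                TweetRecord(
                    id=rec_id,
                    timestamp=ts,
                    text=text,
                    user_id=user,
                    is_retweet=is_retweet,
                    retweet_count=0,
                    country_tag=config.country_tag,
                )
            )

    # fill in realized retweet counts on the originals
    for idx, c in retweet_counts.items():
        old = records[idx]
        records[idx] = TweetRecord(
            id=old.id, timestamp=old.timestamp, text=old.text,
            user_id=old.user_id, is_retweet=old.is_retweet,
            retweet_count=c, country_tag=old.country_tag,
        )

    truth = {
        "phase_onsets": [s.onset for s in config.surges],
        "gt_date": config.gt_date,
        "rates": rates,
        "daily_counts": daily_counts.astype(int),
        "topic_word": topic_word,
        "doc_topic": doc_topic_truth,
        "vocabulary": vocab,
        "daily_topic_mixture": daily_mixture,
        "phase_mixture": phase_mixture,
    }
    return records, truth


def evaluate_recovery(
    truth: Mapping,
    detected_starts: Sequence[date] | None = None,
    fitted_topic_word: np.ndarray | None = None,
    assignments: Mapping[str, int | None] | None = None,
    onset_tolerance_days: int = 1,
) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Onsets are matched greedily by date distance (each detected start used
    at most once; a match must fall within ``onset_tolerance_days``).
    Topics are matched greedily by cosine between topic-word rows; assignment
    accuracy is computed after that matching.  Only the sections whose
    inputs are supplied appear in the report.
    """
    report: dict = {}
    if detected_starts is not None:
        true_onsets = list(truth["phase_onsets"])
        candidates = list(detected_starts)
        matched = 0
        pairs = sorted(
            (abs((d - t).days), ti, di)
            for ti, t in enumerate(true_onsets)
            for di, d in enumerate(candidates)
        )
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if dist > onset_tolerance_days:
                break
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            matched += 1
        report["onset_recall"] = matched / len(true_onsets) if true_onsets else 1.0
        report["n_true_onsets"] = len(true_onsets)
        report["n_detected"] = len(candidates)
    if fitted_topic_word is not None:
        mapping, cosines = align_topics(
            np.asarray(fitted_topic_word), np.asarray(truth["topic_word"])
        )
        report["topic_cosines"] = cosines
        report["topic_cosine_mean"] = float(np.mean(cosines))
        report["topic_mapping"] = mapping
        if assignments is not None:
            # invert: estimated topic j corresponds to true topic i
            est_to_true = {j: i for i, j in enumerate(mapping)}
            doc_truth = truth["doc_topic"]
            n_ok = 0
            n_all = 0
            for rid, est in assignments.items():
                if est is None or rid not in doc_truth:
                    continue
                n_all += 1
                if est_to_true.get(est) == doc_truth[rid]:
                    n_ok += 1
            report["assignment_accuracy"] = n_ok / n_all if n_all else float("nan")
    return report
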