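# tweetphases

Detects **issue-attention topic phases** in daily social-media volume and
extracts per-phase discussion topics. The package is aimed at
infodemiology / risk-communication researchers who monitor how public
discussion of a health crisis (an epidemic outbreak, for instance) rises,
shifts topic, and fades — and who want those shifts demarcated from the
data itself rather than from official announcement calendars.

## The method

Public attention to an issue follows a cycle of surges and decay. The
pipeline locates the surges in a daily tweet-count series `D_t`:

1. **Smooth**: a zero-phase Butterworth low-pass filter (normalized cutoff
   0.2 of Nyquist) removes day-to-day noise, giving `S_t`.
2. **Differentiate**: *velocity* `v_t = S_t − S_{t−1}` and *acceleration*
   `a_t = v_t − v_{t−1}`.
3. **Calibrate**: at the stream's ground-truth anchor date (the country's
   first confirmed case), the thresholds are learned once:
   `v* = ⌊v_GT⌋ + 1`, `a* = ⌊a_GT⌋`.
4. **Detect**: every later date with `0 < v_t < v*` and `a_t > a*`
   (consecutive qualifying days collapsed to the earliest) starts a new
   **topic phase**; phases partition the study window.
5. **Model**: within each phase, tweets are tokenized and an LDA model is
   fitted for every topic count `K ∈ [2, 50]` (words with fewer than 20
   occurrences dropped; 100 training passes); the `K` minimizing perplexity
   `exp(−Σ log p(w)/N)` is selected.
6. **Report**: topics are ranked by tweet count and the minor tail is
   discarded (the retained prefix covers ≥ 75 % of tweets); each major topic
   is exported for human labeling as its top-1000 most-retweeted tweets and
   top-30 keywords. Theme labels (at most two per topic; dual labels weighted
   0.5 each) produce daily theme-trend tables, and Cohen's κ scores
   annotator agreement.

Per phase, the package also reports **tweet depth** — average retweets per
day divided by average original tweets per day, a standardized cascade-depth
measure — along with volume, user counts, country-mention series and topic
diversity (active-theme count and normalized Shannon entropy).

A seeded synthetic-stream generator (`tweetphases.synth_data`) produces
streams with known surge onsets, topic-word distributions, retweet behavior
and country mentions, so every stage can be validated against ground truth.

## Worked example

```python
from datetime import date
from tweetphases import (GeneratorConfig, SurgeEvent, generate_stream,
                         build_daily_series, detect_phases, phase_stats)

window = (date(2020, 1, 1), date(2020, 3, 31))
config = GeneratorConfig(
    window=window,
    surges=(SurgeEvent(date(2020, 1, 15)), SurgeEvent(date(2020, 2, 10))),
    retweet_prob=(0.2, 0.5, 0.7),
    seed=7,
)
records, truth = generate_stream(config)
series = build_daily_series(records, window)
segmentation, thresholds = detect_phases(series, gt_date=truth["gt_date"])

print(f"thresholds: v < {thresholds.v_thresh}, a > {thresholds.a_thresh}")
for stats in phase_stats(records, segmentation):
    print(f"phase {stats.phase_id}: {stats.start} .. {stats.end}  "
          f"tweets={stats.total_tweets}  depth={stats.tweet_depth}")
```

Output:

```
thresholds: v < 113, a > 27.0
phase 0: 2020-01-01 .. 2020-01-15  tweets=1612  depth=0.34
phase 1: 2020-01-16 .. 2020-02-09  tweets=5511  depth=1.05
phase 2: 2020-02-10 .. 2020-03-31  tweets=8442  depth=2.38
```

The stream was generated with surges on Jan 15 and Feb 10; the detector,
calibrated only at the anchor date, recovers the second onset exactly
(phase 2 starts Feb 10). Tweet depth grows across phases because the
generator's retweet probability rises from 0.2 to 0.7 — each original tweet
cascades further as attention intensifies.

The same pipeline is available from the shell:

```bash
tweetphases simulate --config config.yaml --out stream.jsonl
tweetphases ingest --input stream.jsonl --format jsonl --keywords kw.txt --out records.csv
tweetphases phases --series records.series.csv --gt-date 2020-01-16 --out seg.json
tweetphases topics --corpus records.csv --segmentation seg.json --out topics/
tweetphases report --assignments topics/phase1_assignments.csv \
    --records records.csv --label-map labels.json --out report/
```

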