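# Methods

## Phase demarcation

The daily tweet-count series is treated as a proxy for public attention.
Phases are opened at dates where attention re-accelerates: the joint
condition `0 < v_t < v*` and `a_t > a*` (strict inequalities) on the first
and second discrete differences of the smoothed series. The intuition is
that a forthcoming surge announces itself by acceleration before velocity
has grown large; the anchor date — the first confirmed case, always supplied
by the user, never inferred — gives each stream its own calibration of what
"large" means, via `v* = ⌊v_GT⌋ + 1` and `a* = ⌊a_GT⌋`. The `+1` makes the
anchor date itself satisfy the velocity condition; the floor on
acceleration makes it satisfy the acceleration condition. Thresholds are
learned once and never updated.

**Smoothing** is a first-order Butterworth low-pass at normalized cutoff
0.2 (fraction of the Nyquist frequency, i.e. passing fluctuations slower
than ~10 days/cycle), applied forward-backward (`filtfilt`) so that no
dates are shifted. DC gain is exactly 1: constant series pass through
unchanged, and adding a constant to all counts changes neither derivatives
nor segmentation. Whether the cutoff should be read as a fraction of
Nyquist, of the sampling rate, or as an FFT bin is a genuinely open choice;
fraction-of-Nyquist is the default and both the cutoff and filter order are
arguments. The filter requires at least 7 days of data (edge-padding
constraint of the zero-phase filter).

**Derivative form.** Plain differences of the smoothed counts are the
default. Because a velocity threshold within ±1 of its floor only makes
sense when velocities are order-1 to order-100, `compute_derivatives` also
offers `log` (differences of log1p counts) and `ratio` (day-over-day
relative change) forms behind one function, so the definition can be
swapped by configuration without touching the detection logic.

**Run collapse and numbering.** Consecutive qualifying days open one phase
at the earliest day; no minimum phase length is imposed (real streams show
phases as short as five days). Phase 0 runs from the window start to the
day before the anchor; if a start coincides with the window start the empty
leading phase is omitted and logged.

## Topic modeling

Each phase's tweets are one corpus. The vocabulary keeps tokens with at
least 20 occurrences in the phase (inclusive bound); ids are dense and
assigned in first-occurrence order. LDA is fitted by batch variational
inference for each candidate `K` from 2 to 50 with 100 full passes;
perplexity `exp(−Σ n_dw log(θ_d·β_·w) / N)` — computed from the fitted
point estimates, not the variational bound — selects `K`, ties toward
smaller `K`.

Choices made where the procedure is underdetermined:

- **Priors**: symmetric document-topic prior `α = 1/K` and topic-word prior
  `β = 0.01`, both configurable. Only the K-range, the minimum word count
  and the pass count are fixed by the procedure.
- **Perplexity corpus**: training-corpus perplexity by default (no held-out
  split is prescribed anywhere); out-of-sample selection can be obtained by
  splitting the corpus before calling `select_topic_count`.
- **Restarts**: variational inference is sensitive to initialization — a
  single run can split a dominant topic and merge smaller ones. `fit_lda`
  therefore runs 3 restarts from seeds derived deterministically from the
  user seed and keeps the run with the lowest training perplexity.
  Everything remains bit-for-bit reproducible given a seed.
- **Retweets** are included as documents by default (topic prevalence then
  reflects retweet-weighted attention); `--originals-only` excludes them.
  Documents emptied by vocabulary filtering are dropped from fitting but
  retained downstream with a null topic.

## Topic ranking and themes

"Discarding the minor topics that accounted for less than 25% of all
tweets" is read as a cumulative tail rule: topics are sorted by tweet count
descending (ties toward the lower topic id) and the minimal prefix whose
cumulative share reaches 75 % is retained — this matches reported
"75th-percentile" major-topic counts. The alternative per-topic reading
(keep topics whose own share ≥ 25 %) is available as `rule="per_topic"`.

Theme labeling is human work; the package represents its output as an
editable JSON map `{topic_id: [theme] or [theme, theme]}` with at most two
themes per topic. In daily trend tables a dual-labeled topic contributes
0.5 per tweet to each theme, so per-day totals equal labeled tweet counts
exactly. Cohen's κ is computed from the marginal-frequency chance-agreement
formula; the degenerate all-one-label case with perfect agreement is
defined as κ = 1.

## Phase statistics

Averages divide phase totals by calendar days in the phase, both ends
inclusive. Tweet depth is average retweets/day ÷ average originals/day
(0 when there are no originals), rounded half-up to two decimals for
reporting. Users are counted as distinct user ids per day, then averaged —
hence the per-day user average never exceeds the per-day tweet average.
Total tweets are counted directly from records; no identity between the
printed averages and totals is assumed. Country mentions are
case-insensitive substring matches of any name variant, at most one count
per tweet per country. Topic diversity per day is the active-theme count
and the Shannon entropy of the theme mixture normalized by `log` of the
number of themes in the table.

## Synthetic streams

The generator emulates exactly the structure the detector and topic models
assume, nothing more:

- **Volume**: a baseline Poisson rate (default 100 tweets/day) modulated by
  surge events — log-linear rise to a peak multiplier (default 8× over 3
  days), log-linear decay back to baseline (default 10 days). Poisson is
  the simplest count-noise model; real streams are overdispersed and
  weekday-patterned, which this deliberately omits.
- **Anchor**: the simulated first-case announcement falls
  `announcement_lag_days` (default 1) into the first surge — chatter starts
  rising the day before the official announcement. This places the anchor
  where velocity is already high but acceleration is past its peak, so a
  later surge's onset day shows acceleration above, and velocity below, the
  learned thresholds; surge parameters are chosen so onset days satisfy the
  detection condition, which is what the recovery suite verifies (recall
  ≥ 0.9 within ±1 day over 20 seeds).
- **Text**: `k_true` topic-word distributions drawn from a sparse Dirichlet
  (concentration 0.05 over a 200-token default vocabulary → well-separated
  topics); each document draws one topic from its phase's mixture
  (Dirichlet concentration 5, i.e. moderately balanced) and its tokens
  i.i.d. from that topic. Tokens are synthetic (`tok0001`…), sidestepping
  language-specific tokenization; there is no grammar, no hashtags, no
  code-switching, so passing tests show pipeline correctness, not
  readiness for any particular language.
- **Retweets** copy an earlier original's text (exercising text dedup
  concerns) with phase-dependent probability; realized retweet counts are
  written back onto the originals.
- **Volume-coupled diversity**: with `volume_entropy_coupling > 0` the
  daily topic mixture is drawn from a Dirichlet whose concentration shrinks
  as the day's rate rises — busy days concentrate on fewer topics, giving
  the inverse volume-diversity relationship as a generative property.

Recovery scoring matches onsets greedily by date distance (each detection
used once, ±1 day tolerance) and topics greedily by cosine between
topic-word rows; assignment accuracy is computed after that matching.

## Problem sizes

The validation suites run at desk scale: topic recovery uses ~2000
documents over a 500-token nominal vocabulary with `K_true = 3` across 5
seeds; surge recovery uses 20 seeded 91-day streams; the diversity property
uses 10 seeded 60-day streams. These sizes give stable pass/fail behavior
for the properties checked while keeping the full suite in the minutes
range.

## Known limitations

- The velocity/acceleration thresholds assume the anchor date's derivative
  signature generalizes to later surges within the same stream; streams
  whose communication style changes mid-window will mis-calibrate.
- Training-corpus perplexity tends to favor larger `K` than held-out
  perplexity; the selected `K` should be read as an upper bound on
  interpretable topics.
- The built-in tokenizer is whitespace/letter based. Agglutinative and
  unspaced languages need external tokenization upstream (feed pre-spaced
  tokens).
- Annotation-bundle ranking relies on each record's `retweet_count` field
  (default 0 when the source lacks it); records without counts rank by
  timestamp. Input formats that link retweets to their originals instead of
  carrying counts must aggregate those links during ingestion.
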