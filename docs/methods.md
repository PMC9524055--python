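# Methods

This note documents the statistical model behind `tweetwarn`, the
parameter defaults and why they were chosen, what the synthetic stream
generator does and does not emulate, and the package's numerical and
design decisions.

## 1. Problem setting

The system watches a topic-filtered stream of short public posts
("tweets") and tries to raise an alert on the first day a disease topic
is discussed aberrantly often in some region. Three sub-problems follow:

* assign each post to a country (and where possible a first-level
  administrative division) from free text;
* aggregate posts into daily counts per topic and region;
* decide, each day and for each series, whether today's count exceeds
  what the recent past predicts.

A fourth component evaluates such a system against a human
epidemic-intelligence baseline.

## 2. Geolocation

### 2.1 Candidate extraction

Text is tokenised on word characters after blanking URLs and
@-mentions (offsets into the original string are preserved). A logistic
regression over character n-grams (2–4, word-boundary aware) scores each
token's probability of belonging to a place name. It is trained on the
gazetteer's own name tokens (positives) against a multilingual
common-word list (negatives); words appearing in both are treated as
positives, since a token that can name a place must be allowed to reach
the matcher. Maximal runs of consecutive tokens with score ≥
`min_candidate_score` (default 0.5, the natural decision boundary of a
probabilistic classifier) form candidate spans, so "Buenos Aires" is
matched as one query rather than two.

The classifier generalises by shape, not by lookup: unseen words with
place-like morphology can score above 0.5. This is intentional — recall
at this stage is cheap because the matcher and its score threshold do
the filtering — but it means candidate extraction alone is noisy.

### 2.2 Gazetteer matching

Gazetteer entries (countries, first-level divisions, populated places)
are indexed by name token. A candidate span is scored against an entry
as

```
score = Σ_matched idf(t)·boost(t) × coverage × (1 + 0.05·log10(1 + population)) × exact
```

where `idf(t) = 1 + ln(N/df)` over gazetteer names, `boost` is 1.0 for
primary-name tokens and 0.7 for alternate-name tokens, `coverage` is the
fraction of query tokens matched, and `exact` is 3.0 when the candidate
surface equals a full (alternate) name casefold, else 1.0. Ties break by
population, then entry id, so matching is deterministic.

A match is accepted only if its score is **strictly greater than**
`min_score` (default **10**). The scale is calibrated so that an exact
name match on a modest gazetteer scores well above 10 while a partial,
common-token overlap scores well below it; the default therefore trades
recall for precision, which is the right trade for an alerting system
where a false region assignment creates a false series. Raising the
threshold can only remove assignments (the acceptance set is nested in
the threshold), which is verified by test.

Tweet-text location is authoritative; for retweets and quotes the shared
(origin) text is used, since the share itself carries no new place. User
location falls back through geotag → declared location → profile text
and is used for counting only when the text yields nothing.

## 3. Aggregation

Counts are kept per topic × region × day, with regions forming a fixed
hierarchy: country → continent (a bundled 249-row ISO-3166 →
continent table) → an `AMERICA` super-region covering both Americas →
`WORLD`. Posts that cannot be located still count at `WORLD`, so the
global series is conservative. Three counts are maintained: original
posts (`count_original`; retweets and quotes excluded so that
amplification does not masquerade as incidence), all posts
(`count_total`), and posts by trusted accounts (`trusted_count`, a
triage aid shown on alerts). Date ranges are made contiguous with
explicit zeros because a missing day is information for the detector.

## 4. Detection

For a series `y` and day `d`, the baseline is the `baseline_days`
(default **7**) most recent days before `d` (optionally restricted to
the same weekday, in which case 7 baseline points span 7 weeks). The
expected count and alarm threshold are

```
μ̂ = Σ wᵢyᵢ / Σ wᵢ
σ̂² = Σ wᵢ(yᵢ − μ̂)² / (Σ wᵢ − 1)        (0 if Σ wᵢ ≤ 1)
threshold = μ̂ + t₍₁₋α, N−1₎ · σ̂ · sqrt(1 + 1/N)
```

the classical one-sided normal prediction bound for a new observation,
with `N` the number of baseline days and frequency-weight convention for
the variance. A signal is raised iff the observed count is strictly
greater than the threshold; with an all-zero baseline this means a
single post signals, which is the desired behaviour for a series that
has never been discussed. Default `alpha` = **0.025**.

**Downweighting.** A past outbreak in the baseline inflates both μ̂ and
σ̂ and can mask a present one. With downweighting strength
none/low/medium/high, a cutoff `c` = ∞/3/2/1.5 is applied to the
standardised residuals `rᵢ = (yᵢ − μ̂)/σ̂` of a first unweighted pass;
points with `rᵢ > c` (high side only — unusually quiet days are not
evidence against an outbreak) receive weight `(c/rᵢ)²` and the moments
are recomputed. The weight is the squared ratio familiar from
robust-regression downweighting: influence decays quadratically beyond
the cutoff.

Calibration facts, each pinned by an acceptance test with a priori
seeds: the threshold agrees with an independently coded prediction
bound to < 1e-9; over 10 000 simulated in-control Poisson(50) days the
signal rate at nominal α = 0.05 stays within three Monte-Carlo standard
errors of 0.05; and ten-fold injected outbreaks over a Poisson(5)
baseline are caught in ≥ 95% of 200 seeded runs at α = 0.025 with high
downweighting (measured: 100%).

## 5. Evaluation statistics

* **Geolocation accuracy**: per tweet and rater, a prediction matches at
  national level if the country agrees with the rater's gold country,
  at subnational level if the first-level division also agrees;
  disagreeing raters contribute fractionally. Confusion cells follow
  the convention of the surveillance-evaluation literature for this
  design: a tweet the rater could locate counts as true positive if the
  system assigned a location and false positive if it did not; a tweet
  with no extractable location counts as true negative if unassigned
  and false negative if assigned. Sensitivity, specificity, PPV, NPV
  and prevalence follow from the cells.
* **PPV of signals**: specific PPV = events / (events + false signals)
  over evaluated signals; general PPV adds unevaluated alerts to the
  denominator and is therefore a lower bound on precision over
  everything raised.
* **Inter-rater agreement** between the automated and manual arms:
  the share of all evaluated signals found by that arm, with a Wald
  binomial CI `p ± z·sqrt(p(1−p)/n)` (clipped to [0, 1]).
* **Timeliness**: alerts are deduplicated to unique events by
  (topic, subtopic), keeping the earliest validation time per arm;
  events found by both arms yield paired differences in hours
  (automated − manual, negative = earlier), summarised by median and
  IQR (linear interpolation) and tested with a one-sided Wilcoxon
  signed-rank test. Zero differences are dropped; with no ties and
  n ≤ 15 the p-value is exact via dynamic-programming enumeration of
  the signed-rank distribution, otherwise a normal approximation with
  tie correction `−Σ(t³−t)/48` and continuity correction is used. The
  exact branch is verified against brute-force sign enumeration and
  `scipy.stats.wilcoxon`.

Reported percentages are rounded half-up to one decimal for display;
all arithmetic is done unrounded.

## 6. Synthetic stream generator

The generator exists to provide ground truth, not realism. It emulates:
daily post volumes per topic and country as negative binomial (mean λ,
dispersion k; k = ∞ gives Poisson), a configurable share of retweets,
quotes and trusted accounts, four template languages, place mentions
embedded verbatim from the gazetteer with probability
`place_mention_prob`, user-location fields with probability
`user_location_prob`, and multiplicative outbreak injection over a
topic/region/date window. Given a seed the stream is bit-reproducible
(a single generator consumed in sorted topic/country/day order).

It does **not** emulate: diurnal posting patterns, misspellings or
nicknames of places, sarcasm or negation, bot bursts, network structure
of retweets, or correlated multi-country outbreaks. Conclusions about
linguistic robustness of the geolocation step therefore cannot be drawn
from synthetic data; the generator's role is closed-loop verification
(the embedded place's country is the label) and detector calibration,
where only the count process matters.

Problem sizes used in tests and the acceptance script (10 000 null days,
200 power runs, ~10-day demonstration streams, a 20-entry toy gazetteer)
are this package's own choices, sized to keep the full suite under a
minute while leaving Monte-Carlo error well below the margins being
tested.

## 7. Design and numerical decisions

* The Student-t prediction bound is computed via `scipy.stats.t.ppf`;
  no closed-form approximations.
* Weighted moments use the frequency-weight convention (denominator
  `Σw − 1`) so that unit weights reduce exactly to the ddof = 1 sample
  estimators.
* Strict inequality at both thresholds (match score, alarm) so that
  degenerate flat series and score ties err on the side of silence —
  except the all-zero baseline, where any activity exceeds the bound.
* Records, configs and evaluation inputs are pydantic models with
  validating invariants (e.g. a retweet cannot also be a quote;
  `trusted_count ≤ count_original ≤ count_total`; a validated event must
  carry a validation time). Malformed input files fail with the line or
  column named.
* Everything is deterministic given a seed: generator, classifier
  training, matching tie-breaks, file output ordering. Re-running the
  pipeline on the same input produces byte-identical outputs.

## 8. Limitations

* The bundled gazetteer is a 20-entry toy for tests and demos; real use
  requires a full GeoNames extract, and score calibration around the
  default threshold of 10 should be re-checked at that scale.
* The detector assumes approximate normality of daily counts; for very
  low-count series the prediction bound is conservative rather than
  exact, and the strict-inequality rule means single-post signals on
  previously silent series — filter by `trusted_pct` or raise baselines
  if that is too sensitive.
* The seven-day default baseline reacts to weekday seasonality;
  `same_weekday_only` trades a longer memory (7 weeks) for that.
* Geolocation resolves to one location per post; posts naming several
  places keep only the best-scoring one.
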