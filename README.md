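# tweetwarn

Early-warning epidemic surveillance from a public social-media stream.
`tweetwarn` turns a stream of topic-filtered tweet records into daily
topic-by-region counts, flags statistically aberrant days with a
modified-EARS threshold, and ships the full statistical toolkit needed to
evaluate such a system against human epidemic intelligence: geolocation
accuracy with confusion-matrix metrics, general and specific positive
predictive value, inter-rater agreement with Wald confidence intervals,
alert deduplication, and detection timeliness with a one-sided Wilcoxon
signed-rank test.

Because real tweet collections cannot be redistributed, the package
includes a seeded synthetic stream generator with outbreak injection, so
every stage — geolocation, aggregation, detection, evaluation — can be
exercised and tested end to end with known ground truth.

## The pipeline

1. **Stream** (`tweetwarn.stream`). A tweet record carries text, language,
   timestamps, retweet/quote flags and optional user-location fields. The
   generator draws daily counts per topic and country from a negative
   binomial (Poisson in the limit), writes short templated texts in four
   languages that embed gazetteer place names verbatim, and can multiply
   the rate of one topic/region over a date window to inject an outbreak.

2. **Geolocation** (`tweetwarn.geo`). A two-step gazetteer approach.
   First, a trainable character-n-gram logistic-regression classifier
   scores each token's likelihood of being part of a place name; maximal
   runs of high-scoring tokens become candidate spans, so multi-word names
   stay together. Second, candidates are matched against a GeoNames-style
   gazetteer with a vector-space score: inverse-document-frequency weights
   over name tokens, coverage of the query, a population boost, and an
   exact-name boost. A match is accepted only if its score exceeds a
   threshold (default 10). Tweet-text location takes priority; user
   location (geotag, then declared location, then profile) is the
   fallback.

3. **Aggregation** (`tweetwarn.aggregate`). Records are counted per topic,
   day and region, where a country propagates to its continent, the
   Americas also to an `AMERICA` super-region, and everything to `WORLD`.
   Three counts are kept: original tweets (retweets/quotes excluded),
   total posts, and posts from trusted accounts.

4. **Detection** (`tweetwarn.detect`). For each series the expected count
   is the (weighted) mean of the trailing baseline window (default 7
   days), and the alarm threshold is the one-sided upper prediction bound

   `threshold = mean + t(1 − alpha, N − 1) · sd · sqrt(1 + 1/N)`

   with default `alpha = 0.025`. Past outbreaks are prevented from
   inflating the baseline by downweighting: baseline points whose
   standardised residual exceeds a cutoff `c` (strength low/medium/high →
   `c` = 3/2/1.5) get weight `(c/r)²`, and the mean and standard deviation
   are recomputed with those weights. A day with observed count strictly
   above the threshold raises a signal; signals become alert records with
   top-word summaries and the share of trusted posts.

5. **Evaluation** (`tweetwarn.evaluate`). Everything needed to audit such
   a system: geolocation accuracy at national and subnational level with
   sensitivity/specificity/PPV/NPV from rater annotations; PPV of signals
   against triage outcomes, both over evaluated signals (specific) and
   over all raised alerts (general); inter-rater agreement between the
   automated and a manual surveillance arm; Wald binomial confidence
   intervals; deduplication of alerts into unique events; and detection
   timeliness (hours earlier/later than the comparator) summarised by
   median/IQR and tested with a one-sided Wilcoxon signed-rank test (exact
   for small tie-free samples, normal approximation with tie and
   continuity correction otherwise).

## Worked example

Simulate ten days of measles chatter in France (about 5 original tweets a
day) with an eight-fold outbreak injected on the last day, then run the
whole pipeline as of that evening:

```python
import datetime as dt
from tweetwarn import OutbreakSpec, StreamSpec, TopicRates, generate_stream, write_tweets
from tweetwarn.config import PipelineConfig
from tweetwarn.pipeline import build_geo_resources

entries, _, _ = build_geo_resources(PipelineConfig(seed=42))
french_places = [e for e in entries if e.country == "FR"]

spec = StreamSpec(
    topics=[TopicRates(name="measles", rates={"FR": 5.0})],
    start_date=dt.date(2020, 10, 1),
    end_date=dt.date(2020, 10, 10),
    place_mention_prob=0.9,
    user_location_prob=0.0,
    seed=42,
)
outbreak = OutbreakSpec(
    topic="measles", region="FR",
    start=dt.date(2020, 10, 10), end=dt.date(2020, 10, 10), magnitude=8,
)
records = generate_stream(spec, french_places, [outbreak])
write_tweets(records, "outbreak.jsonl")
```

```text
$ tweetwarn run outbreak.jsonl --as-of 2020-10-10T18:00:00+00:00 --seed 42 -v
INFO tweetwarn: read 90 records from outbreak.jsonl
INFO tweetwarn: geolocate: 83/90 records resolved to a country
INFO tweetwarn: aggregate: 3 topic×region series
INFO tweetwarn: detect: 3 signals at 2020-10-10T18:00:00+00:00
INFO tweetwarn: run: 3 series, 3 alerts -> out
```

The daily counts show a flat baseline of 1–6 original tweets and the
burst day at 23:

```text
$ head -11 out/counts.csv
topic,region,date,count_original,count_total,trusted_count
measles,EU,2020-10-01,6,7,0
measles,EU,2020-10-02,2,3,0
measles,EU,2020-10-03,1,3,0
measles,EU,2020-10-04,4,5,0
measles,EU,2020-10-05,2,3,0
measles,EU,2020-10-06,5,6,1
measles,EU,2020-10-07,3,4,0
measles,EU,2020-10-08,3,6,2
measles,EU,2020-10-09,5,7,0
measles,EU,2020-10-10,23,39,1
```

and the outbreak raises alerts in France and every enclosing region:

```text
$ cut -d, -f1-4,6 out/alerts.csv
date,hour,topic,region,tweet_count
2020-10-10,18,measles,EU,23
2020-10-10,18,measles,FR,23
2020-10-10,18,measles,WORLD,26
```

Evaluation works from triage tables. Given two arms that both found a
French measles outbreak (the automated arm 39 hours earlier) and a shared
cholera cluster, plus one false signal and one unevaluated alert:

```text
$ tweetwarn evaluate report --triage triage.csv && cat report.txt
Signal-detection evaluation
  alerts 5  events 3  false signals 1  not evaluated 1
  PPV_g 60.0%  PPV_s 75.0%
  IRA automated 75.0% (95% CI 32.6-100.0)
  IRA manual 50.0% (95% CI 1.0-99.0)
  timeliness median -19.5 h (IQR -29.2 to -9.8); Wilcoxon W+ 0.0, one-sided p 0.5
```

The same steps are available individually (`tweetwarn simulate`,
`geolocate`, `aggregate`, `detect`) and programmatically via
`tweetwarn.pipeline.run_pipeline` / `run_evaluation`.

## Methods

See [docs/methods.md](docs/methods.md) for the statistical model,
parameter defaults and their rationale, numerical choices, and known
limitations.
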