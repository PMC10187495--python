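# tweetsent

Lexicon-based polarity analysis of German crisis-communication tweets.

During the first year of the COVID-19 pandemic in Germany, health
authorities and independent experts communicated heavily on Twitter. A
standard way to quantify the emotional tone of such corpora is the
*lexicon approach*: every word of a tweet is looked up in a fixed polarity
dictionary, and the tweet's sentiment is the sum of the matched word
weights. `tweetsent` packages this analysis end to end for two-group,
phase-structured tweet corpora, for researchers in health crisis
communication and infodemiology who want a reproducible, auditable
pipeline rather than a one-off script.

## The method

Given a polarity lexicon *L* assigning each word form *w* a weight
*p(w) ∈ [−1, +1] \ {0}* (SentiWS v2.0 format: separate positive and
negative files, lemmas with POS tags and inflected forms), the score of a
tweet *t* with word tokens *w₁ … wₙ* is the plain sum

  s(t) = Σᵢ p(wᵢ) · 1[wᵢ ∈ L]

with no negation handling, length normalisation or deduplication — a
strict single-word analysis. A tweet is classed positive (s > 0),
negative (s < 0) or neutral (s = 0). Before scoring, the corpus passes a
four-stage filter cascade with per-stage bookkeeping: study window
(2020-01-01 to 2021-01-15), topic keywords, originality (retweets, quotes
and replies dropped), and language tag. Retained tweets are aggregated
into arithmetic mean polarities per actor group (authority vs. expert) and
pandemic phase (phase 1 to 2020-03-22, phase 2 to 2020-10-28, phase 3 to
2021-01-15, Europe/Berlin calendar days), into top-k positive/negative
word tables per phase, and into weekly positive/negative tweet counts
plotted against the daily infection incidence divided by 100.

Because the original Twitter corpus is not publicly available, the package
ships a synthetic-corpus generator with known ground truth (configurable
cell means, contamination rates and a two-wave incidence curve) and a
small synthetic lexicon fixture in SentiWS dialect, so the entire pipeline
is testable offline. Point it at a real SentiWS download and a harvested
corpus to run the analysis for real.

## Worked example

`examples/worked_example/` holds twelve hand-written tweets, a small
incidence table and a config. From the repository root:

```bash
tweetsent analyze --config examples/worked_example/config.yaml --out out/
```

prints `analyzed 8 tweets -> out` — of the 12 inputs, one tweet is out of
window, one off-topic, one a retweet and one non-German. `out/scored.csv`
then starts

```
id,group,phase,score,sign_class,n_tokens,n_matches
t01,authority,1,-0.8732,negative,7,2
t02,expert,1,-1.9672,negative,9,3
t03,authority,1,1.0452,positive,7,3
```

t01 ("Das Risiko steigt, bitte Kontakte vermeiden. #Corona") matches
Risiko (−0.5367) and vermeiden (−0.3365), so s = −0.8732: a negative
tweet. `out/summary.csv` gives the group × phase means,

```
group,phase_id,n_tweets,mean_polarity,n_positive,n_negative,n_neutral
authority,1,2,0.086000,1,1,0
authority,2,2,0.245850,2,0,0
expert,1,1,-1.967200,0,1,0
expert,2,1,-0.840800,0,1,0
expert,3,2,-0.108950,1,1,0
```

— in this toy corpus experts tweet more negatively than authorities in
every phase. `out/top_words.csv` ranks the matched lemmas per phase and
sign, and `out/weekly.csv` holds the weekly counts with the scaled
incidence (e.g. week 2020-W13 shows incidence_scaled 50.00, i.e. 5000
daily infections / 100). `tweetsent report --analysis-dir out/` renders
the phase-mean bar chart and the weekly overlay as PNGs.

`tweetsent simulate --seed 1 --out sim/` generates a full synthetic corpus
(12 000 tweets under the default study conditions), its ground truth and
an incidence curve; the expected per-tweet scores in
`examples/worked_example/expected_scored.csv` were computed with an
independent brute-force scorer.

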