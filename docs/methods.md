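# Methods

## Scoring model

The package implements dictionary-based polarity scoring. A sentiment
lexicon in SentiWS v2.0 dialect supplies signed word weights in
[−1, +1] \ {0}; a tweet's score is the exact sum of the weights of its
matched word tokens, in token order. The model is deliberately minimal —
single-word matching with no negation scope, intensifiers, POS
disambiguation or length normalisation — because that is the analysis the
pipeline is built to audit, and every additional device would change the
quantity being reported. Consequences worth keeping in mind:

- a tweet with no lexicon match scores exactly 0 and is classed
  *neutral*; neutral tweets stay in the denominator of cell means by
  default (`include_neutral=False` switches to polar-only means);
- longer tweets can reach larger |s|; means over corpora with different
  length distributions are comparable only under this raw-sum convention;
- repeated words count once per occurrence.

### Tokenisation

URLs and @-mentions are removed, `#` is stripped from hashtags (the stem
remains a word), and the text splits on every character that is not a
Unicode letter or an inner hyphen; digits and emoji therefore drop out.
Casing is preserved at tokenisation and folded at lookup, because German
nouns are capitalised in the lexicon but inconsistently in tweets.

### Lookup and homographs

The lexicon index maps every case-folded lemma *and* inflected form to
its entries (`match_inflections=False` restricts to lemmas). When several
entries share a surface form, lookup resolves to the entry with the
largest |weight|; an exact-magnitude tie resolves to the negative entry.
This rule is deterministic and biases toward the stronger signal; with no
POS tagger in the pipeline no linguistically better rule is available.

## Filter cascade

Corpora pass four pure predicates in a fixed order — study window, topic
keywords, originality, language — each reporting its removal count, with
removals + retained = input enforced as an invariant. The final retained
*set* is order-invariant; the order only attributes removals to stages.
Topic matching is case-folded substring search over the text with URLs
and mentions excised and hashtag stems included; the keyword list is a
configuration item (default: corona, covid, sars-cov-2, pandemie,
lockdown, impfstoff, inzidenz) and every run records the list it used.
The language filter trusts the record's language tag; no language
detection model is introduced. Phase windows are inclusive calendar-day
ranges evaluated in a configurable timezone (default Europe/Berlin, since
Twitter timestamps are UTC but the study windows are German calendar
days). Default phases: 2020-01-01..2020-03-22, 2020-03-23..2020-10-28,
2020-10-29..2021-01-15.

## Aggregation

Cell means are arithmetic means of raw per-tweet sums; empty (group,
phase) cells raise `EmptyCellError` rather than reporting 0, so absent
data can never masquerade as neutrality. Top-k word tables count matched
lemmas per token occurrence (not per tweet), pooled over both groups by
default, ranked by count with alphabetical tie-break. Weekly series bin
tweets by ISO-8601 week of the local calendar date; neutral tweets enter
neither count; the daily incidence curve is sampled at each week's
Thursday (the ISO reference day, configurable) and divided by 100, the
conventional scaling for co-plotting daily infections with weekly tweet
counts.

## Synthetic corpus generator

The generator emulates the *structure* of a two-group crisis-communication
corpus, not its language: texts are bags of lexicon surface forms, neutral
filler words (a fixed 50-word list disjoint from the lexicon) and one
topic keyword. What it reproduces, with defaults:

- **cells**: 2 groups × 3 phases, `n_per_cell` = 2000 tweets each;
- **target mean polarity** μ per cell, default authorities
  (−0.05, −0.005, −0.03) and experts (−0.12, −0.09, −0.07): authorities
  near neutral with phase 2 closest to zero, experts clearly more
  negative in every phase, most negative at onset;
- **tweet length** ~ Poisson(18) tokens (floor 3), roughly a 280-character
  German tweet; each token is a lexicon emission with probability
  `p_lex = 0.10`, i.e. λ ≈ 1.8 polar words per tweet;
- **contamination**: independent per-tweet Bernoulli draws — off-topic
  0.50, non-original (retweet/quote/reply, uniform kind) 0.76, non-German
  0.03. Jointly these make ≈ 23 % of topic tweets survive the originality
  and language stages, the retention reported for real crisis corpora of
  this kind;
- **incidence**: a sum of Gaussian waves, default peaks ≈ 5 500/day around
  2020-03-25 (width 9 d) and ≈ 22 000/day around 2020-12-18 (width 24 d),
  the shape of Germany's first pandemic year.

Emission targets the cell mean exactly in expectation: an emitted word is
positive with probability q solving q·w̄⁺ + (1−q)·w̄⁻ = μ/λ (w̄± the
lexicon's per-sign mean weights); a configuration whose μ/λ falls outside
[w̄⁻, w̄⁺] is rejected up front. The sign sequence is *systematic*
(a Bresenham stream whose running positive share tracks q exactly) rather
than i.i.d., so the sign mix contributes no sampling variance; entries
within a sign are drawn uniformly. The cell-mean standard error recorded
in the ground truth is therefore

  SE = sqrt( λ·(q·Var⁺ + (1−q)·Var⁻ + (μ/λ)²) / n )

(within-sign weight dispersion plus the Poisson count term). The
`variance_mode="paired"` option instead gives every topic tweet exactly
one word of a fixed strong pair (Freude 0.6502 / Gefahr −0.6922) mixed
deterministically, which pins the cell mean to within (w⁺−w⁻)/n of μ with
zero sampling variance — useful for small-n exact tests; a literal
exact-μ multiset is unreachable for arbitrary μ with a finite 4-decimal
lexicon. Ground truth additionally records, per cell, the realized mean
of the emitted weight sums over clean tweets — the value a correct
pipeline must recover to float precision — and cascade-ordered
contamination counts that the filter report must match exactly.

Each (group, phase) cell draws from `default_rng([seed, group, phase])`,
so resizing one cell leaves all others bit-identical. Timestamps are
uniform over the phase window (07:00–23:00 local); corpora are emitted in
timestamp order.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: German syntax and morphology beyond listed
inflections, negation ("nicht gut"), irony, hashtag conventions, account
heterogeneity, burstiness of tweet timing, correlation between sentiment
and incidence, and lexical drift over phases. Tests against it validate
the pipeline's arithmetic, filtering and bookkeeping, not the linguistic
validity of lexicon scoring.

## Bundled fixture lexicon

`tweetsent/data/sentiws_*.txt` is a 40-entry synthetic fixture in SentiWS
v2.0 dialect (20 positive, 20 negative), not an excerpt of the SentiWS
distribution. It carries the two canonical example weights (Freude
0.6502, schädlich −0.9269) and the frequent crisis-vocabulary words used
throughout the tests, with plausible invented weights: negatives
stronger on average than positives, as in the real lexicon. Entry weights
keep their exact decimal strings so files round-trip byte-identically.

## Numerical and design choices

- Scores are plain float sums in token order; the generator accumulates
  in the same order, so truth and pipeline agree to ~1e-16 (tests compare
  per-tweet scores exactly and cell means at 1e-12).
- CSV outputs round scores to 4 decimals (sums of 4-decimal weights are
  exact at that precision) and means to 6; all outputs are deterministic
  functions of inputs and seed, and reruns are byte-identical.
- `sign_class` uses exact comparison with 0; only genuinely cancelling or
  matchless tweets are neutral.
- Naive timestamps are interpreted as UTC; phase assignment always
  converts to the scheme's timezone first.
- Simulation sizes in tests (tens to 2000 tweets per cell) keep the whole
  suite in seconds while leaving the 3-SE recovery checks well-powered.

## Limitations

Lexicon scoring measures word-level connotation, not communicative
intent: "verlangsamen" (slow down) carries a negative weight even when it
reports a success. The pipeline inherits every such bias of its lexicon.
Group comparisons are descriptive — no significance testing is provided,
by design. Emotion categories (fear, anger, joy, sadness) are out of
scope: a polarity lexicon cannot distinguish them.
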