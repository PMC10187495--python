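"""Tokenisation and additive per-tweet polarity scoring.

Scoring is a strict single-word ("Einzelwort") lexicon match: the tweet text
is split into words, each word is looked up independently in the polarity
lexicon, and the matched weights are summed to one signed score per tweet.
There is no negation handling, no intensifiers and no length normalisation;
words repeated in a tweet count once per occurrence.  A tweet with no match
scores exactly 0 and is classed neutral.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .lexicon import SentimentLexicon, bundled_lexicon, load_lexicon

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Tweet

__all__ = [
    "Match",
    "ScoredTweet",
    "tokenize",
    "strip_urls_mentions",
    "score_tokens",
    "score_tweet",
    "score_corpus",
    "sign_class",
    "LexiconPolarityScorer",
]

URL_RE = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)
MENTION_RE = re.compile(r"@\w+")
# words: unicode letters plus inner hyphens; digits, emoji, punctuation split
TOKEN_RE = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*")


def strip_urls_mentions(text: str) -> str:
    """Remove URLs and @-mentions; they never take part in word matching."""
    return MENTION_RE.sub(" ", URL_RE.sub(" ", text))


def tokenize(text: str) -> list[str]:
    """Split tweet text into words.

    URLs and @-mentions are removed, the '#' of hashtags is stripped (the
    hashtag stem stays a word), and the remainder is split on everything
    that is not a letter (umlauts and ß included) or an inner hyphen.
    Digits and emoji are dropped; casing is preserved — the lexicon
    case-folds at lookup.
    """
    cleaned = strip_urls_mentions(text).replace("#", " ")
    return TOKEN_RE.findall(cleaned)


class Match(NamedTuple):
    """One token that hit the lexicon, with the resolved entry's weight."""

    token: str
    weight: float
    lemma: str


def sign_class(score: float) -> str:
    """positive / negative / neutral by the sign of the summed score."""
    if score > 0:
        return "positive"
    if score < 0:
        return "negative"
    return "neutral"


@dataclass
class ScoredTweet:
    """A tweet with its tokens, lexicon matches and summed polarity."""

    tweet: "Tweet"
    tokens: list[str]
    matches: list[Match]
    score: float
    sign_class: str


def score_tokens(
    tokens: Sequence[str], lexicon: SentimentLexicon
) -> tuple[list[Match], float, str]:
    """Look every token up independently and sum the matched weights.

    Returns (matches, score, sign_class).  Tokens absent from the lexicon
    contribute nothing and are not recorded; the sum runs in token order.
    """
    matches: list[Match] = []
    score = 0.0
    for token in tokens:
        entry = lexicon.lookup(token)
        if entry is not None:
            matches.append(Match(token, entry.weight, entry.lemma.casefold()))
            score += entry.weight
    return matches, score, sign_class(score)


def score_tweet(tweet: "Tweet", lexicon: SentimentLexicon) -> ScoredTweet:
    tokens = tokenize(tweet.text)
    matches, score, cls = score_tokens(tokens, lexicon)
    return ScoredTweet(tweet=tweet, tokens=tokens, matches=matches, score=score, sign_class=cls)


def score_corpus(tweets: Iterable["Tweet"], lexicon: SentimentLexicon) -> list[ScoredTweet]:
    """Score every tweet independently, preserving corpus order."""
    return [score_tweet(t, lexicon) for t in tweets]


class LexiconPolarityScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: raw texts -> additive polarity scores.

    ``fit`` builds the surface-form index (from the given SentiWS-dialect
    file pair, or from the bundled fixture lexicon when no paths are set);
    ``transform`` maps an iterable of texts to a float array of per-text
    scores, so the scorer drops into sklearn pipelines as a feature
    extractor.

    Parameters
    ----------
    positive_path, negative_path : str or None
        SentiWS-dialect lexicon files.  Both or neither must be given.
    match_inflections : bool
        Index listed inflected forms in addition to lemmas (default True).
    """

    def __init__(
        self,
        positive_path: str | None = None,
        negative_path: str | None = None,
        match_inflections: bool = True,
    ) -> None:
        self.positive_path = positive_path
        self.negative_path = negative_path
        self.match_inflections = match_inflections

    def fit(self, X=None, y=None) -> "LexiconPolarityScorer":
        if (self.positive_path is None) != (self.negative_path is None):
            raise ValueError("give both lexicon paths or neither")
        if self.positive_path is None:
            self.lexicon_ = bundled_lexicon(match_inflections=self.match_inflections)
        else:
            self.lexicon_ = load_lexicon(
                self.positive_path, self.negative_path,
                match_inflections=self.match_inflections,
            )
        self.n_entries_ = len(self.lexicon_)
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "lexicon_"):
            raise ValueError("LexiconPolarityScorer is not fitted yet; call fit first")
        scores = [score_tokens(tokenize(text), self.lexicon_)[1] for text in X]
        return np.asarray(scores, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["polarity_score"], dtype=object)
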