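"""Synthetic two-group tweet corpus with known polarity ground truth.

The generator emulates the structure of the study corpus — two actor groups
(authorities and independent experts) tweeting across three pandemic phases
— with a known, configurable mean polarity per (group, phase) cell, plus
the contaminants the filter cascade is meant to remove: off-topic tweets,
retweets/quotes/replies, and non-German tweets.  It also produces a
two-wave daily incidence curve for the weekly overlay.

Clean tweet text is assembled from fixture-lexicon surface forms, neutral
filler words and one topic keyword; lexicon words are sampled so the
expected per-tweet score equals the cell's target mean.  Each (group,
phase) cell draws from its own deterministic sub-stream of the seed, so
changing one cell's size leaves every other cell's tweets unchanged.

It makes no attempt at realistic German syntax, hashtag culture or
retweet dynamics — it exercises the pipeline's arithmetic and filtering,
not language understanding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from importlib import resources
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np

from .corpus import (
    DEFAULT_KEYWORDS,
    PhaseScheme,
    Tweet,
    default_phase_scheme,
)
from .lexicon import LexiconEntry, SentimentLexicon, bundled_lexicon

__all__ = [
    "GeneratorConfig",
    "CellTruth",
    "GroundTruth",
    "ConfigError",
    "Wave",
    "generate_corpus",
    "generate_incidence",
    "load_filler_words",
]

GROUPS = ("authority", "expert")


class ConfigError(ValueError):
    """An unsatisfiable or inconsistent generator configuration."""


@dataclass(frozen=True)
class Wave:
    """One Gaussian-shaped incidence wave: center date, peak height, width (days)."""

    center: date
    height: float
    width_days: float

    def __post_init__(self) -> None:
        if self.width_days <= 0:
            raise ConfigError("wave width must be > 0")
        if self.height < 0:
            raise ConfigError("wave height must be >= 0")


#: First wave March 2020 (peak ~5500/day), second wave from autumn 2020
#: (peak ~22000/day around mid-December) — the shape of Germany's first
#: pandemic year.
DEFAULT_WAVES: tuple[Wave, ...] = (
    Wave(date(2020, 3, 25), 5500.0, 9.0),
    Wave(date(2020, 12, 18), 22000.0, 24.0),
)


def _default_n() -> dict[str, tuple[int, int, int]]:
    return {"authority": (2000, 2000, 2000), "expert": (2000, 2000, 2000)}


def _default_mu() -> dict[str, tuple[float, float, float]]:
    # authorities near neutral, closest to zero in phase 2; experts clearly
    # more negative in every phase, most negative at pandemic onset
    return {"authority": (-0.05, -0.005, -0.03), "expert": (-0.12, -0.09, -0.07)}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``n_per_cell`` counts the tweets generated per (group, phase) cell;
    contamination attributes are independent per-tweet Bernoulli draws, so
    the clean (retained-after-cascade) count per cell is binomial around
    ``n * (1-off_topic) * (1-non_original) * (1-non_german)``.  Default
    contamination rates make roughly 23 % of topic tweets survive the
    originality and language filters, the fraction reported for the study
    corpus.  Target cell means are enforced in expectation through the
    lexicon-word emission mix ("sampled" mode: entries are drawn at random
    but the positive/negative sign sequence is systematic, so the sign mix
    contributes no sampling variance) or near-exactly through a
    deterministic two-word pairing ("paired" mode, zero sampling variance).
    """

    seed: int = 0
    n_per_cell: Mapping[str, Sequence[int]] = field(default_factory=_default_n)
    mu: Mapping[str, Sequence[float]] = field(default_factory=_default_mu)
    mean_tokens: float = 18.0
    p_lex: float = 0.10
    off_topic_fraction: float = 0.50
    non_original_fraction: float = 0.76
    non_german_fraction: float = 0.03
    scheme: PhaseScheme = field(default_factory=default_phase_scheme)
    keywords: Sequence[str] = DEFAULT_KEYWORDS
    variance_mode: str = "sampled"  # or "paired"
    lowercase_prob: float = 0.3
    inflection_prob: float = 0.4
    waves: Sequence[Wave] = DEFAULT_WAVES
    non_german_lang: str = "en"

    def validate(self, lexicon: SentimentLexicon) -> None:
        for name in ("off_topic_fraction", "non_original_fraction",
                     "non_german_fraction", "lowercase_prob", "inflection_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} = {value} outside [0, 1]")
        if not 0.0 < self.p_lex <= 1.0:
            raise ConfigError(f"p_lex = {self.p_lex} outside (0, 1]")
        if self.mean_tokens <= 0:
            raise ConfigError("mean_tokens must be > 0")
        if self.variance_mode not in ("sampled", "paired"):
            raise ConfigError(f"unknown variance_mode {self.variance_mode!r}")
        if set(self.n_per_cell) != set(self.mu):
            raise ConfigError("n_per_cell and mu must cover the same groups")
        n_phases = len(self.scheme.phases)
        pos_mean, neg_mean = _sign_means(lexicon)
        lam = self.mean_tokens * self.p_lex
        for group, counts in self.n_per_cell.items():
            if len(counts) != n_phases or len(self.mu[group]) != n_phases:
                raise ConfigError(f"group {group!r}: need one n and one mu per phase")
            for phase_idx, (n, mu) in enumerate(zip(counts, self.mu[group])):
                if n < 0:
                    raise ConfigError(f"negative n for cell ({group}, phase {phase_idx + 1})")
                per_emission = mu / lam
                if not neg_mean <= per_emission <= pos_mean:
                    raise ConfigError(
                        f"cell ({group}, phase {phase_idx + 1}): target mean {mu} "
                        f"unreachable with p_lex*L = {lam:.2f} and lexicon sign means "
                        f"[{neg_mean:.4f}, {pos_mean:.4f}]"
                    )


@dataclass
class CellTruth:
    """Generator bookkeeping for one (group, phase) cell."""

    group: str
    phase_id: int
    mu_target: float
    n_generated: int
    n_clean: int
    #: mean of the emitted-weight sums over the cell's clean tweets (the
    #: exact value a correct pipeline must recover)
    realized_mean: float
    #: analytic standard error of the clean-cell mean under the emission
    #: distribution (compound-Poisson variance / n_clean)
    expected_se: float


@dataclass
class GroundTruth:
    """Per-cell truth plus cascade-ordered contamination bookkeeping."""

    cells: list[CellTruth]
    removed_out_of_window: int
    removed_off_topic: int
    removed_non_original: int
    removed_non_language: int
    n_clean_total: int
    n_generated_total: int

    def cell(self, group: str, phase_id: int) -> CellTruth:
        for cell in self.cells:
            if cell.group == group and cell.phase_id == phase_id:
                return cell
        raise KeyError((group, phase_id))

    def to_json(self, **kwargs) -> str:
        payload = {
            "cells": [asdict(c) for c in self.cells],
            "removed_out_of_window": self.removed_out_of_window,
            "removed_off_topic": self.removed_off_topic,
            "removed_non_original": self.removed_non_original,
            "removed_non_language": self.removed_non_language,
            "n_clean_total": self.n_clean_total,
            "n_generated_total": self.n_generated_total,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


def load_filler_words() -> list[str]:
    """The bundled 50-word neutral filler vocabulary (lexicon-disjoint)."""
    text = (resources.files("tweetsent") / "data" / "filler_words.txt").read_text("utf-8")
    return [w for w in text.splitlines() if w]


def _sign_means(lexicon: SentimentLexicon) -> tuple[float, float]:
    pos = [e.weight for e in lexicon.entries if e.weight > 0]
    neg = [e.weight for e in lexicon.entries if e.weight < 0]
    if not pos or not neg:
        raise ConfigError("lexicon must contain both positive and negative entries")
    return float(np.mean(pos)), float(np.mean(neg))


def _sign_variances(lexicon: SentimentLexicon) -> tuple[float, float]:
    """Within-sign weight variances (positive entries, negative entries)."""
    pos = np.array([e.weight for e in lexicon.entries if e.weight > 0])
    neg = np.array([e.weight for e in lexicon.entries if e.weight < 0])
    return float(pos.var()), float(neg.var())


def _surface(entry: LexiconEntry, rng: np.random.Generator, config: GeneratorConfig) -> str:
    form = entry.lemma
    if entry.inflections and rng.random() < config.inflection_prob:
        form = entry.inflections[rng.integers(len(entry.inflections))]
    if rng.random() < config.lowercase_prob:
        form = form.lower()
    return form


# strong positive / strong negative pair used by the deterministic
# "paired" variance mode (one emission per tweet, Bresenham mixing)
_PAIR_LEMMAS = ("Freude", "Gefahr")


def _cell_stream(config: GeneratorConfig, group_idx: int, phase_idx: int,
                 purpose: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, group_idx, phase_idx, purpose])


def generate_corpus(
    config: GeneratorConfig,
    lexicon: SentimentLexicon | None = None,
) -> tuple[list[Tweet], GroundTruth]:
    """Generate the corpus and its ground truth, deterministic in the seed.

    The returned corpus is sorted by timestamp (ties by id).  Contamination
    bookkeeping follows the cascade order (topic → originality → language):
    a tweet that is both off-topic and a retweet counts as an off-topic
    removal, exactly as the cascade would remove it.
    """
    lexicon = lexicon or bundled_lexicon()
    config.validate(lexicon)
    filler = load_filler_words()
    pos_entries = [e for e in lexicon.entries if e.weight > 0]
    neg_entries = [e for e in lexicon.entries if e.weight < 0]
    pair_a = next(e for e in lexicon.entries if e.lemma == _PAIR_LEMMAS[0])
    pair_b = next(e for e in lexicon.entries if e.lemma == _PAIR_LEMMAS[1])
    pos_mean, neg_mean = _sign_means(lexicon)
    lam = config.mean_tokens * config.p_lex
    zone = ZoneInfo(config.scheme.tz)
    keywords = [str(k) for k in config.keywords]

    groups = sorted(config.n_per_cell)
    tweets: list[Tweet] = []
    cells: list[CellTruth] = []
    removed = {"off_topic": 0, "non_original": 0, "non_language": 0}
    counter = 0

    for group_idx, group in enumerate(groups):
        handles = [f"{group}_{i:02d}" for i in range(1, 6)]
        for phase_idx, phase in enumerate(config.scheme.phases):
            n = int(config.n_per_cell[group][phase_idx])
            mu = float(config.mu[group][phase_idx])
            rng = _cell_stream(config, group_idx, phase_idx)
            if config.variance_mode == "paired":
                q_pair = (mu - pair_b.weight) / (pair_a.weight - pair_b.weight)
                if not 0.0 <= q_pair <= 1.0:
                    raise ConfigError(
                        f"cell ({group}, phase {phase_idx + 1}): target mean {mu} outside "
                        f"the paired range [{pair_b.weight}, {pair_a.weight}]"
                    )
            else:
                q_pos = (mu / lam - neg_mean) / (pos_mean - neg_mean)
                # validate() guarantees 0 <= q_pos <= 1
                var_pos, var_neg = _sign_variances(lexicon)
            phase_days = (phase.end - phase.start).days + 1

            clean_scores: list[float] = []
            n_paired_a = 0
            # systematic (Bresenham) sign stream over the cell's emissions:
            # the running positive share tracks q_pos exactly, removing the
            # sign-mix sampling variance from the cell mean
            n_emitted = 0
            n_emitted_pos = 0
            for i in range(n):
                counter += 1
                off_topic = rng.random() < config.off_topic_fraction
                non_original = rng.random() < config.non_original_fraction
                non_german = rng.random() < config.non_german_fraction
                day = phase.start + timedelta(days=int(rng.integers(phase_days)))
                moment = datetime.combine(
                    day, time(hour=int(rng.integers(7, 23)),
                              minute=int(rng.integers(60)),
                              second=int(rng.integers(60))),
                    tzinfo=zone,
                )
                n_tokens = max(3, int(rng.poisson(config.mean_tokens)))

                words: list[str] = []
                weight_sum = 0.0
                if off_topic:
                    words = [filler[rng.integers(len(filler))] for _ in range(n_tokens)]
                else:
                    if config.variance_mode == "paired":
                        # Bresenham mixing: cumulative share of pair_a tracks q_pair
                        use_a = math.floor((i + 1) * q_pair) > math.floor(i * q_pair)
                        entry = pair_a if use_a else pair_b
                        n_paired_a += int(use_a)
                        words = [filler[rng.integers(len(filler))]
                                 for _ in range(max(n_tokens - 1, 1))]
                        slot = int(rng.integers(len(words) + 1))
                        words.insert(slot, _surface(entry, rng, config))
                        weight_sum = entry.weight
                    else:
                        for _ in range(n_tokens):
                            if rng.random() < config.p_lex:
                                n_emitted += 1
                                emit_pos = (
                                    math.floor(n_emitted * q_pos)
                                    > math.floor((n_emitted - 1) * q_pos)
                                )
                                if emit_pos:
                                    n_emitted_pos += 1
                                    entry = pos_entries[rng.integers(len(pos_entries))]
                                else:
                                    entry = neg_entries[rng.integers(len(neg_entries))]
                                words.append(_surface(entry, rng, config))
                                weight_sum += entry.weight
                            else:
                                words.append(filler[rng.integers(len(filler))])
                    keyword = keywords[rng.integers(len(keywords))]
                    slot = int(rng.integers(len(words) + 1))
                    words.insert(slot, keyword.capitalize())

                flags = {"is_retweet": False, "is_quote": False, "is_reply": False}
                if non_original:
                    kind = ("is_retweet", "is_quote", "is_reply")[int(rng.integers(3))]
                    flags[kind] = True
                lang = config.non_german_lang if non_german else "de"

                tweets.append(Tweet(
                    id=f"t{counter:07d}",
                    created_at=moment,
                    author=handles[int(rng.integers(len(handles)))],
                    group=group,
                    text=" ".join(words),
                    lang=lang,
                    **flags,
                ))

                # cascade-ordered bookkeeping
                if off_topic:
                    removed["off_topic"] += 1
                elif non_original:
                    removed["non_original"] += 1
                elif non_german:
                    removed["non_language"] += 1
                else:
                    clean_scores.append(weight_sum)

            n_clean = len(clean_scores)
            if config.variance_mode == "paired":
                se = 0.0  # deterministic emission: no sampling variance
            elif n_clean:
                # Var(cell mean) ≈ λ (q Var_pos + (1-q) Var_neg + m1²) / n:
                # entry dispersion within each sign plus the Poisson count
                # term; the sign mix itself is systematic (no variance)
                m1 = mu / lam
                per_tweet_var = lam * (q_pos * var_pos + (1 - q_pos) * var_neg + m1**2)
                se = math.sqrt(per_tweet_var / n_clean)
            else:
                se = float("nan")
            cells.append(CellTruth(
                group=group,
                phase_id=phase.phase_id,
                mu_target=mu,
                n_generated=n,
                n_clean=n_clean,
                realized_mean=(sum(clean_scores) / n_clean) if n_clean else float("nan"),
                expected_se=se,
            ))

    tweets.sort(key=lambda t: (t.created_at, t.id))
    truth = GroundTruth(
        cells=cells,
        removed_out_of_window=0,
        removed_off_topic=removed["off_topic"],
        removed_non_original=removed["non_original"],
        removed_non_language=removed["non_language"],
        n_clean_total=sum(c.n_clean for c in cells),
        n_generated_total=len(tweets),
    )
    return tweets, truth


def generate_incidence(config: GeneratorConfig) -> list[tuple[date, int]]:
    """Daily infection counts over the study window: a sum of Gaussian waves.

    Deterministic — the curve is a fixed function of the wave parameters.
    """
    for wave in config.waves:
        Wave(wave.center, wave.height, wave.width_days)  # re-validate
    series: list[tuple[date, int]] = []
    day = config.scheme.start
    while day <= config.scheme.end:
        total = 0.0
        for wave in config.waves:
            dt_days = (day - wave.center).days
            total += wave.height * math.exp(-0.5 * (dt_days / wave.width_days) ** 2)
        series.append((day, int(round(total))))
        day += timedelta(days=1)
    return series
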