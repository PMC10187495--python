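"""Group/phase polarity means, top-k polarity words, weekly counts.

All aggregates are descriptive.  Means are arithmetic means of the raw
per-tweet score sums over every tweet in a (group, phase) cell — neutral
(zero-score) tweets stay in the denominator by default, matching a design
in which the corpus size is the denominator, not the number of polar
tweets.  Empty cells raise instead of reporting a silent zero.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import IO, Iterable, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

from .corpus import PhaseScheme, assign_phase, DEFAULT_TIMEZONE
from .scoring import ScoredTweet

__all__ = [
    "GroupPhaseSummary",
    "EmptyCellError",
    "mean_polarity",
    "summarize_cells",
    "top_k_words",
    "weekly_series",
    "read_incidence",
    "scored_table",
    "plot_phase_means",
    "plot_weekly_overlay",
]


class EmptyCellError(ValueError):
    """A (group, phase) cell with no tweets — there is no mean to report."""


@dataclass(frozen=True)
class GroupPhaseSummary:
    group: str
    phase_id: int
    n_tweets: int
    mean_polarity: float
    n_positive: int
    n_negative: int
    n_neutral: int


def _in_cell(st: ScoredTweet, group: str | None, phase: int | None,
             scheme: PhaseScheme) -> bool:
    if group is not None and st.tweet.group != group:
        return False
    if phase is not None and assign_phase(st.tweet, scheme) != phase:
        return False
    return True


def mean_polarity(
    scored: Sequence[ScoredTweet],
    group: str,
    phase: int,
    scheme: PhaseScheme,
    include_neutral: bool = True,
) -> GroupPhaseSummary:
    """Arithmetic mean of per-tweet scores in one (group, phase) cell.

    ``include_neutral=False`` drops zero-score tweets from the denominator
    (and the numerator, where they contribute nothing anyway).
    """
    cell = [st for st in scored if _in_cell(st, group, phase, scheme)]
    if not include_neutral:
        cell = [st for st in cell if st.sign_class != "neutral"]
    if not cell:
        raise EmptyCellError(f"no tweets for group={group!r}, phase={phase}")
    classes = Counter(st.sign_class for st in cell)
    return GroupPhaseSummary(
        group=group,
        phase_id=phase,
        n_tweets=len(cell),
        mean_polarity=sum(st.score for st in cell) / len(cell),
        n_positive=classes.get("positive", 0),
        n_negative=classes.get("negative", 0),
        n_neutral=classes.get("neutral", 0),
    )


def summarize_cells(
    scored: Sequence[ScoredTweet],
    scheme: PhaseScheme,
    include_neutral: bool = True,
) -> pd.DataFrame:
    """One row per non-empty (group, phase) cell, groups sorted, phases in order.

    Empty cells are absent rows, never zero rows.
    """
    groups = sorted({st.tweet.group for st in scored})
    rows = []
    for group in groups:
        for ph in scheme.phases:
            try:
                summary = mean_polarity(scored, group, ph.phase_id, scheme,
                                        include_neutral=include_neutral)
            except EmptyCellError:
                continue
            rows.append(asdict(summary))
    columns = ["group", "phase_id", "n_tweets", "mean_polarity",
               "n_positive", "n_negative", "n_neutral"]
    return pd.DataFrame(rows, columns=columns)


def top_k_words(
    scored: Sequence[ScoredTweet],
    phase: int,
    polarity_sign: int,
    scheme: PhaseScheme,
    k: int = 5,
    group: str | None = None,
) -> list[tuple[str, int]]:
    """Most frequent matched lemmas of one sign within one phase.

    Counting is per token occurrence across both actor groups (restrict with
    ``group``); the reported word is the matched entry's case-folded lemma.
    Ranking is by count descending with alphabetical tie-break; at most
    ``k`` rows are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if polarity_sign not in (1, -1):
        raise ValueError("polarity_sign must be +1 or -1")
    counts: Counter[str] = Counter()
    for st in scored:
        if not _in_cell(st, group, phase, scheme):
            continue
        for match in st.matches:
            if (1 if match.weight > 0 else -1) == polarity_sign:
                counts[match.lemma] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# ---------------------------------------------------------------------------
# weekly series and incidence

def read_incidence(source: str | Path | IO[str]) -> list[tuple[date, int]]:
    """Read a daily incidence CSV (columns: date, count), sorted by date.

    Duplicate dates and negative counts are rejected.
    """
    df = pd.read_csv(source)
    missing = {"date", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"incidence CSV missing columns: {sorted(missing)}")
    days = pd.to_datetime(df["date"]).dt.date
    if days.duplicated().any():
        dup = days[days.duplicated()].iloc[0]
        raise ValueError(f"duplicate incidence date {dup}")
    counts = pd.to_numeric(df["count"])
    if (counts < 0).any():
        raise ValueError("negative incidence count")
    series = sorted(zip(days, counts.astype(int)))
    return [(d, int(c)) for d, c in series]


def _iso_week_key(day: date) -> tuple[int, int]:
    iso = day.isocalendar()
    return iso.year, iso.week


def _iso_week_label(key: tuple[int, int]) -> str:
    return f"{key[0]}-W{key[1]:02d}"


def _iso_week_thursday(key: tuple[int, int]) -> date:
    return date.fromisocalendar(key[0], key[1], 4)


def _next_iso_week(key: tuple[int, int]) -> tuple[int, int]:
    return _iso_week_key(_iso_week_thursday(key) + timedelta(days=7))


def weekly_series(
    scored: Sequence[ScoredTweet],
    incidence: Sequence[tuple[date, int]] | None = None,
    tz: str = DEFAULT_TIMEZONE,
) -> pd.DataFrame:
    """Weekly counts of positive and negative tweets with incidence overlay.

    Tweets are binned by the ISO week of their local calendar date; neutral
    tweets enter neither count.  The incidence curve is sampled at each
    week's Thursday and divided by 100, the scaling used to co-plot daily
    infections with weekly tweet counts.  Weeks run contiguously from the
    first to the last tweet's week; an empty corpus yields an empty frame.
    """
    columns = ["iso_week", "n_positive", "n_negative", "incidence_scaled"]
    if not scored:
        return pd.DataFrame(columns=columns)
    zone = ZoneInfo(tz)
    by_week: dict[tuple[int, int], list[int]] = {}
    for st in scored:
        key = _iso_week_key(st.tweet.created_at.astimezone(zone).date())
        cell = by_week.setdefault(key, [0, 0])
        if st.sign_class == "positive":
            cell[0] += 1
        elif st.sign_class == "negative":
            cell[1] += 1
    lookup = dict(incidence or ())
    rows = []
    key, last = min(by_week), max(by_week)
    while key <= last:
        pos, neg = by_week.get(key, (0, 0))
        rows.append({
            "iso_week": _iso_week_label(key),
            "n_positive": pos,
            "n_negative": neg,
            "incidence_scaled": lookup.get(_iso_week_thursday(key), 0) / 100.0,
        })
        key = _next_iso_week(key)
    return pd.DataFrame(rows, columns=columns)


def scored_table(
    scored: Sequence[ScoredTweet], scheme: PhaseScheme
) -> pd.DataFrame:
    """Flat per-tweet table: id, group, phase, score, sign_class, sizes."""
    rows = [
        {
            "id": st.tweet.id,
            "group": st.tweet.group,
            "phase": assign_phase(st.tweet, scheme),
            "score": st.score,
            "sign_class": st.sign_class,
            "n_tokens": len(st.tokens),
            "n_matches": len(st.matches),
        }
        for st in scored
    ]
    return pd.DataFrame(
        rows, columns=["id", "group", "phase", "score", "sign_class", "n_tokens", "n_matches"]
    )


def write_top_words_csv(
    scored: Sequence[ScoredTweet],
    scheme: PhaseScheme,
    stream: IO[str],
    k: int = 5,
) -> None:
    """Top-k positive and negative lemmas per phase as one long CSV."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["phase", "sign", "rank", "word", "count"])
    for ph in scheme.phases:
        for sign, label in ((1, "positive"), (-1, "negative")):
            ranking = top_k_words(scored, ph.phase_id, sign, scheme, k=k)
            for rank, (word, count) in enumerate(ranking, start=1):
                writer.writerow([ph.phase_id, label, rank, word, count])


# ---------------------------------------------------------------------------
# plotting (optional rendering of the two headline figures)

def plot_phase_means(summary: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of mean polarity per phase, one bar group per actor group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    groups = sorted(summary["group"].unique())
    phases = sorted(summary["phase_id"].unique())
    width = 0.8 / max(len(groups), 1)
    for i, group in enumerate(groups):
        sub = summary[summary["group"] == group].set_index("phase_id")
        values = [sub["mean_polarity"].get(ph, float("nan")) for ph in phases]
        ax.bar([p + i * width for p in range(len(phases))], values, width, label=group)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks([p + width * (len(groups) - 1) / 2 for p in range(len(phases))])
    ax.set_xticklabels([f"phase {ph}" for ph in phases])
    ax.set_ylabel("mean polarity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_weekly_overlay(weekly: pd.DataFrame, path: str | Path) -> None:
    """Weekly positive/negative tweet counts with the scaled incidence curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    x = range(len(weekly))
    ax.plot(x, weekly["n_positive"], color="tab:blue", label="positive tweets")
    ax.plot(x, weekly["n_negative"], color="tab:red", label="negative tweets")
    ax.plot(x, weekly["incidence_scaled"], color="tab:green", linestyle=":",
            label="daily new infections / 100")
    step = max(len(weekly) // 12, 1)
    ax.set_xticks(list(x)[::step])
    ax.set_xticklabels(weekly["iso_week"][::step], rotation=45, ha="right")
    ax.set_ylabel("tweets per week")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
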