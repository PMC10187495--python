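"""Tweet corpus model, JSONL/CSV I/O, filter cascade and pandemic phases.

The study corpus is built by a four-stage cascade applied in a fixed order:

1. study window — keep tweets dated inside the phase scheme's span,
2. topic       — keep tweets whose text contains a topic keyword,
3. originality — drop retweets, quotes and replies,
4. language    — keep tweets carrying the configured language tag.

Per-stage removal counts are reported so the cascade is auditable; the final
retained set is order-independent (each stage is a pure predicate) even
though per-stage counts depend on the order.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timezone
from pathlib import Path
from typing import IO, Iterable, Sequence
from zoneinfo import ZoneInfo

from .scoring import strip_urls_mentions

__all__ = [
    "Tweet",
    "Phase",
    "PhaseScheme",
    "FilterReport",
    "CorpusFormatError",
    "DEFAULT_KEYWORDS",
    "default_phase_scheme",
    "read_corpus",
    "read_corpus_jsonl",
    "read_corpus_csv",
    "write_corpus_jsonl",
    "write_corpus_csv",
    "filter_window",
    "filter_topic",
    "filter_original",
    "filter_language",
    "assign_phase",
    "apply_cascade",
]

#: Default topic keyword list (the study's own list is not published; this
#: default is configurable and every run records the list actually used).
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "corona", "covid", "sars-cov-2", "pandemie", "lockdown", "impfstoff", "inzidenz",
)

DEFAULT_TIMEZONE = "Europe/Berlin"

TWEET_FIELDS = (
    "id", "created_at", "author", "group", "text", "lang",
    "is_retweet", "is_quote", "is_reply",
)


class CorpusFormatError(ValueError):
    """A malformed corpus record; carries the offending line number."""

    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"record at line {line_number}: {message}")


@dataclass(frozen=True)
class Tweet:
    """One message: text plus the metadata the cascade filters on."""

    id: str
    created_at: datetime
    author: str
    group: str
    text: str
    lang: str
    is_retweet: bool = False
    is_quote: bool = False
    is_reply: bool = False

    def __post_init__(self) -> None:
        if self.is_retweet and self.is_quote:
            raise ValueError(f"tweet {self.id}: cannot be both retweet and quote")
        if self.created_at.tzinfo is None:
            # naive timestamps are taken as UTC, Twitter's native clock
            object.__setattr__(self, "created_at", self.created_at.replace(tzinfo=timezone.utc))

    @property
    def is_original(self) -> bool:
        return not (self.is_retweet or self.is_quote or self.is_reply)


@dataclass(frozen=True)
class Phase:
    phase_id: int
    start: date  # inclusive
    end: date    # inclusive


@dataclass(frozen=True)
class PhaseScheme:
    """Ordered, non-overlapping, contiguous calendar windows (inclusive days)."""

    phases: tuple[Phase, ...]
    tz: str = DEFAULT_TIMEZONE

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("phase scheme needs at least one phase")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if prev.end >= cur.start:
                raise ValueError(f"phases {prev.phase_id} and {cur.phase_id} overlap")
            if (cur.start - prev.end).days != 1:
                raise ValueError(
                    f"gap between phase {prev.phase_id} and {cur.phase_id}: "
                    f"{prev.end} .. {cur.start}"
                )
        for ph in self.phases:
            if ph.start > ph.end:
                raise ValueError(f"phase {ph.phase_id} starts after it ends")

    @property
    def start(self) -> date:
        return self.phases[0].start

    @property
    def end(self) -> date:
        return self.phases[-1].end

    def local_date(self, moment: datetime) -> date:
        return moment.astimezone(ZoneInfo(self.tz)).date()

    def assign(self, moment: datetime) -> int | None:
        """Phase id containing the moment's calendar date, or None."""
        day = self.local_date(moment)
        for ph in self.phases:
            if ph.start <= day <= ph.end:
                return ph.phase_id
        return None

    def contains(self, moment: datetime) -> bool:
        return self.assign(moment) is not None


def default_phase_scheme(tz: str = DEFAULT_TIMEZONE) -> PhaseScheme:
    """The first pandemic year, split at the lockdown end and the second wave:

    phase 1: 2020-01-01 .. 2020-03-22 (onset through first lockdown),
    phase 2: 2020-03-23 .. 2020-10-28 (post-lockdown through summer plateau),
    phase 3: 2020-10-29 .. 2021-01-15 (second wave and vaccine debate).
    """
    return PhaseScheme(
        phases=(
            Phase(1, date(2020, 1, 1), date(2020, 3, 22)),
            Phase(2, date(2020, 3, 23), date(2020, 10, 28)),
            Phase(3, date(2020, 10, 29), date(2021, 1, 15)),
        ),
        tz=tz,
    )


@dataclass
class FilterReport:
    """Per-stage removal bookkeeping; removals plus retained = input."""

    n_input: int = 0
    removed_out_of_window: int = 0
    removed_off_topic: int = 0
    removed_non_original: int = 0
    removed_non_language: int = 0
    n_retained: int = 0

    def check_conservation(self) -> bool:
        return (
            self.removed_out_of_window + self.removed_off_topic
            + self.removed_non_original + self.removed_non_language
            + self.n_retained
        ) == self.n_input

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)


# ---------------------------------------------------------------------------
# corpus I/O

def _parse_bool(value, lineno: int, key: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no", ""):
            return False
    raise CorpusFormatError(lineno, f"field {key!r}: not a boolean: {value!r}")


def _record_to_tweet(record: dict, lineno: int, seen_ids: set[str]) -> Tweet:
    for key in TWEET_FIELDS[:6]:
        if key not in record or record[key] is None or record[key] == "":
            if key == "text" and record.get(key) == "":
                continue  # empty text is a valid (neutral) tweet
            raise CorpusFormatError(lineno, f"missing required field {key!r}")
    tid = str(record["id"])
    if tid in seen_ids:
        raise CorpusFormatError(lineno, f"duplicate tweet id {tid!r}")
    seen_ids.add(tid)
    try:
        created = datetime.fromisoformat(str(record["created_at"]))
    except ValueError:
        raise CorpusFormatError(
            lineno, f"unparseable ISO-8601 timestamp {record['created_at']!r}"
        ) from None
    flags = {
        key: _parse_bool(record.get(key, False), lineno, key)
        for key in ("is_retweet", "is_quote", "is_reply")
    }
    try:
        return Tweet(
            id=tid,
            created_at=created,
            author=str(record["author"]),
            group=str(record["group"]),
            text=str(record.get("text", "")),
            lang=str(record["lang"]),
            **flags,
        )
    except ValueError as exc:
        raise CorpusFormatError(lineno, str(exc)) from None


def read_corpus_jsonl(stream: Iterable[str]) -> list[Tweet]:
    """One JSON object per line; order preserved, ids must be unique."""
    tweets: list[Tweet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(lineno, f"invalid JSON: {exc.msg}") from None
        if not isinstance(record, dict):
            raise CorpusFormatError(lineno, "record is not a JSON object")
        tweets.append(_record_to_tweet(record, lineno, seen))
    return tweets


def read_corpus_csv(stream: IO[str]) -> list[Tweet]:
    """RFC-4180 CSV with a header row carrying the JSONL keys."""
    reader = csv.DictReader(stream)
    tweets: list[Tweet] = []
    seen: set[str] = set()
    # header occupies line 1
    for lineno, record in enumerate(reader, start=2):
        tweets.append(_record_to_tweet(record, lineno, seen))
    return tweets


def read_corpus(path: str | Path) -> list[Tweet]:
    """Read a corpus file; the format is taken from the extension."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        if path.suffix.lower() == ".csv":
            return read_corpus_csv(fh)
        return read_corpus_jsonl(fh)


def _tweet_record(tweet: Tweet) -> dict:
    return {
        "id": tweet.id,
        "created_at": tweet.created_at.isoformat(),
        "author": tweet.author,
        "group": tweet.group,
        "text": tweet.text,
        "lang": tweet.lang,
        "is_retweet": tweet.is_retweet,
        "is_quote": tweet.is_quote,
        "is_reply": tweet.is_reply,
    }


def write_corpus_jsonl(tweets: Iterable[Tweet], stream: IO[str]) -> None:
    for tweet in tweets:
        stream.write(json.dumps(_tweet_record(tweet), ensure_ascii=False) + "\n")


def write_corpus_csv(tweets: Iterable[Tweet], stream: IO[str]) -> None:
    writer = csv.DictWriter(stream, fieldnames=TWEET_FIELDS, lineterminator="\n")
    writer.writeheader()
    for tweet in tweets:
        record = _tweet_record(tweet)
        record.update({k: str(record[k]).lower() for k in ("is_retweet", "is_quote", "is_reply")})
        writer.writerow(record)


def corpus_to_jsonl_string(tweets: Iterable[Tweet]) -> str:
    buf = io.StringIO()
    write_corpus_jsonl(tweets, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# filters

def filter_window(
    tweets: Sequence[Tweet], scheme: PhaseScheme
) -> tuple[list[Tweet], int]:
    """Keep tweets whose local calendar date falls inside the scheme span."""
    retained = [t for t in tweets if scheme.contains(t.created_at)]
    return retained, len(tweets) - len(retained)


def _matchable_text(text: str) -> str:
    # mentions and URLs do not take part in keyword matching; hashtag stems do
    return strip_urls_mentions(text).replace("#", " ").casefold()


def filter_topic(
    tweets: Sequence[Tweet], keywords: Sequence[str]
) -> tuple[list[Tweet], int]:
    """Keep tweets whose text contains at least one keyword as a substring.

    Matching is case-folded; hashtag text participates ('#' stripped) while
    @-mentions and URLs are excluded.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    folded = [k.casefold() for k in keywords]
    retained = [
        t for t in tweets
        if any(k in _matchable_text(t.text) for k in folded)
    ]
    return retained, len(tweets) - len(retained)


def filter_original(tweets: Sequence[Tweet]) -> tuple[list[Tweet], int]:
    """Drop retweets, quotes and replies; keep originally authored tweets."""
    retained = [t for t in tweets if t.is_original]
    return retained, len(tweets) - len(retained)


def filter_language(
    tweets: Sequence[Tweet], lang: str = "de"
) -> tuple[list[Tweet], int]:
    """Keep tweets whose language tag equals ``lang`` (case-insensitive)."""
    target = lang.casefold()
    retained = [t for t in tweets if t.lang.casefold() == target]
    return retained, len(tweets) - len(retained)


def assign_phase(tweet: Tweet, scheme: PhaseScheme) -> int | None:
    """Phase id of the tweet's local calendar date; None if out of window."""
    return scheme.assign(tweet.created_at)


def apply_cascade(
    tweets: Sequence[Tweet],
    scheme: PhaseScheme | None = None,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    lang: str = "de",
) -> tuple[list[Tweet], FilterReport]:
    """Window → topic → originality → language, with removal bookkeeping."""
    scheme = scheme or default_phase_scheme()
    report = FilterReport(n_input=len(tweets))
    stage, report.removed_out_of_window = filter_window(tweets, scheme)
    stage, report.removed_off_topic = filter_topic(stage, keywords)
    stage, report.removed_non_original = filter_original(stage)
    stage, report.removed_non_language = filter_language(stage, lang)
    report.n_retained = len(stage)
    return stage, report
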