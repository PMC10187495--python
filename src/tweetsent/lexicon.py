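"""SentiWS-format polarity lexicon parsing and inflection-aware lookup.

SentiWS (Sentiment-Wortschatz, University of Leipzig) is a German polarity
lexicon distributed as two plain-text files, one for positive and one for
negative words.  Each line has the dialect::

    <lemma>|<POS><TAB><weight>[<TAB><infl1>,<infl2>,...]

where the weight is a signed decimal in [-1, +1] (never 0: only polar words
are listed) and the optional third field lists inflected surface forms.
Lookup is case-folded because tweets rarely respect German noun
capitalisation, and matches both lemmas and inflections by default.

The files bundled under ``tweetsent/data/`` are a small synthetic fixture in
the same dialect (they are not an excerpt of the SentiWS distribution); they
exist so that the package is testable and runnable without any download.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "LexiconEntry",
    "SentimentLexicon",
    "SentiwsParseError",
    "SignConsistencyError",
    "parse_sentiws",
    "build_lexicon",
    "lookup_polarity",
    "entry_to_line",
    "load_lexicon",
    "bundled_lexicon",
    "bundled_lexicon_paths",
    "write_lexicon_tsv",
]


class SentiwsParseError(ValueError):
    """A lexicon line that does not conform to the SentiWS dialect."""

    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class SignConsistencyError(SentiwsParseError):
    """A weight whose sign contradicts the file it was read from."""


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon lemma with its POS tag, polarity weight and inflections.

    ``weight_str`` preserves the exact decimal string from the source file so
    that entries serialise back byte-identically (floats alone would not).
    """

    lemma: str
    pos_tag: str
    weight: float
    inflections: tuple[str, ...] = ()
    weight_str: str = ""

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("lemma must be non-empty")
        if not -1.0 <= self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside [-1, 1]")
        if self.weight == 0.0:
            raise ValueError("weight 0 is not a polar word")
        if len(set(self.inflections)) != len(self.inflections):
            raise ValueError(f"duplicate inflections for {self.lemma!r}")
        if not self.weight_str:
            object.__setattr__(self, "weight_str", repr(self.weight))

    @property
    def sign(self) -> int:
        return 1 if self.weight > 0 else -1

    def surface_forms(self) -> Iterator[str]:
        """Lemma followed by every inflection, original casing."""
        yield self.lemma
        yield from self.inflections


def parse_sentiws(stream: Iterable[str], expected_sign: int) -> list[LexiconEntry]:
    """Parse one SentiWS-dialect file into entries.

    Parameters
    ----------
    stream
        Iterable of text lines (an open file works).
    expected_sign
        +1 for the positive file, -1 for the negative file.  A line whose
        weight sign contradicts it raises :class:`SignConsistencyError`.
    """
    if expected_sign not in (1, -1):
        raise ValueError("expected_sign must be +1 or -1")
    entries: list[LexiconEntry] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise SentiwsParseError(
                lineno, f"expected 2 or 3 TAB-separated fields, got {len(fields)}"
            )
        head, weight_text = fields[0], fields[1]
        if "|" not in head:
            raise SentiwsParseError(lineno, f"missing '|' between lemma and POS in {head!r}")
        lemma, _, pos_tag = head.rpartition("|")
        try:
            weight = float(weight_text)
        except ValueError:
            raise SentiwsParseError(lineno, f"non-numeric weight {weight_text!r}") from None
        if not -1.0 <= weight <= 1.0:
            raise SentiwsParseError(lineno, f"weight {weight_text} outside [-1, 1]")
        if weight == 0.0:
            raise SentiwsParseError(lineno, "weight 0 is not a polar word")
        if (1 if weight > 0 else -1) != expected_sign:
            raise SignConsistencyError(
                lineno,
                f"weight {weight_text} contradicts expected sign "
                f"{'+' if expected_sign > 0 else '-'}",
            )
        inflections: tuple[str, ...] = ()
        if len(fields) == 3 and fields[2]:
            inflections = tuple(f for f in fields[2].split(",") if f)
        try:
            entry = LexiconEntry(
                lemma=lemma, pos_tag=pos_tag, weight=weight,
                inflections=inflections, weight_str=weight_text,
            )
        except ValueError as exc:
            raise SentiwsParseError(lineno, str(exc)) from None
        entries.append(entry)
    return entries


def entry_to_line(entry: LexiconEntry) -> str:
    """Serialise an entry back to its SentiWS dialect line (no newline)."""
    line = f"{entry.lemma}|{entry.pos_tag}\t{entry.weight_str}"
    if entry.inflections:
        line += "\t" + ",".join(entry.inflections)
    return line


@dataclass
class SentimentLexicon:
    """Case-folded surface-form index over positive and negative entries.

    ``surface_index`` maps every case-folded lemma or inflection to the list
    of entries carrying that form; homographs are stored side by side and
    only resolved at lookup time (strongest absolute weight wins, the
    negative entry on an exact-magnitude tie).
    """

    entries: list[LexiconEntry]
    surface_index: dict[str, list[LexiconEntry]] = field(repr=False)
    n_positive: int = 0
    n_negative: int = 0
    match_inflections: bool = True

    def lookup(self, token: str) -> LexiconEntry | None:
        """Resolve a token to a single lexicon entry, or None if unknown."""
        candidates = self.surface_index.get(token.casefold())
        if not candidates:
            return None
        # strongest |weight| wins; exact-magnitude ties resolve negative
        return max(candidates, key=lambda e: (abs(e.weight), -e.sign))

    def lookup_weight(self, token: str) -> float | None:
        entry = self.lookup(token)
        return None if entry is None else entry.weight

    @property
    def max_abs_weight(self) -> float:
        return max(abs(e.weight) for e in self.entries) if self.entries else 0.0

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(
    positive_entries: Iterable[LexiconEntry],
    negative_entries: Iterable[LexiconEntry],
    match_inflections: bool = True,
) -> SentimentLexicon:
    """Assemble the surface index from separately parsed entry lists.

    With ``match_inflections=False`` only lemmas are indexed (lemma-only
    matching); the default indexes every listed inflected form too.
    """
    positive = list(positive_entries)
    negative = list(negative_entries)
    entries = positive + negative
    index: dict[str, list[LexiconEntry]] = {}
    for entry in entries:
        forms = entry.surface_forms() if match_inflections else (entry.lemma,)
        seen: set[str] = set()
        for form in forms:
            key = form.casefold()
            if key in seen:  # lemma duplicated in its own inflection list
                continue
            seen.add(key)
            index.setdefault(key, []).append(entry)
    return SentimentLexicon(
        entries=entries,
        surface_index=index,
        n_positive=len(positive),
        n_negative=len(negative),
        match_inflections=match_inflections,
    )


def lookup_polarity(lexicon: SentimentLexicon, token: str) -> float | None:
    """Polarity weight of a token, or None when no surface form matches."""
    return lexicon.lookup_weight(token)


def load_lexicon(
    positive_path: str | Path,
    negative_path: str | Path,
    match_inflections: bool = True,
) -> SentimentLexicon:
    """Read the two SentiWS-dialect files and build the combined lexicon."""
    with open(positive_path, encoding="utf-8") as fh:
        positive = parse_sentiws(fh, expected_sign=1)
    with open(negative_path, encoding="utf-8") as fh:
        negative = parse_sentiws(fh, expected_sign=-1)
    return build_lexicon(positive, negative, match_inflections=match_inflections)


def bundled_lexicon_paths() -> tuple[Path, Path]:
    """Paths of the bundled synthetic fixture lexicon (positive, negative)."""
    data = resources.files("tweetsent") / "data"
    return Path(str(data / "sentiws_positive.txt")), Path(str(data / "sentiws_negative.txt"))


def bundled_lexicon(match_inflections: bool = True) -> SentimentLexicon:
    """The synthetic fixture lexicon shipped with the package."""
    pos, neg = bundled_lexicon_paths()
    return load_lexicon(pos, neg, match_inflections=match_inflections)


def write_lexicon_tsv(lexicon: SentimentLexicon, stream: IO[str] = sys.stdout) -> None:
    """Dump a lexicon as normalised TSV: lemma, POS, weight, inflections."""
    for entry in lexicon.entries:
        stream.write(
            f"{entry.lemma}\t{entry.pos_tag}\t{entry.weight_str}\t"
            + ",".join(entry.inflections)
            + "\n"
        )
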