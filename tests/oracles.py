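"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately naive: linear scans over the raw lexicon entry list with its
own regexes, no shared lookup code with the package implementation.
"""

from __future__ import annotations

import re

_URL = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)
_MENTION = re.compile(r"@\w+")
_WORD = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*")


def oracle_tokenize(text: str) -> list[str]:
    cleaned = _MENTION.sub(" ", _URL.sub(" ", text)).replace("#", " ")
    return _WORD.findall(cleaned)


def oracle_lookup(token: str, entries) -> float | None:
    """Linear scan over every entry's lemma and inflections."""
    folded = token.casefold()
    candidates = []
    for entry in entries:
        for form in (entry.lemma, *entry.inflections):
            if form.casefold() == folded:
                candidates.append(entry.weight)
                break
    if not candidates:
        return None
    # strongest magnitude wins, negative on exact-magnitude ties
    candidates.sort(key=lambda w: (abs(w), -(1 if w > 0 else -1)))
    return candidates[-1]


def oracle_score_text(text: str, entries) -> float:
    score = 0.0
    for token in oracle_tokenize(text):
        weight = oracle_lookup(token, entries)
        if weight is not None:
            score += weight
    return score
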