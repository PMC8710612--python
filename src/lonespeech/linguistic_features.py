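"""Linguistic features from response transcripts.

Positive/negative word counts on the four sentiment-eliciting questions
(childhood activity, earthquake plan, travel plan, traditional event) and
filler-word proportion on all eight questions: 2 x 4 + 1 x 8 = 16 features
per session.

Tokenization is pluggable: the default splits on whitespace and lowercases
(identity lemmatizer), which is exact for the bundled synthetic language.
A morphological analyzer for a real language can be registered under a
name and selected via the tokenizer spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

#: question ids whose transcripts are scored for sentiment
SENTIMENT_QUESTIONS = frozenset({3, 6, 7, 8})

QUESTION_IDS = tuple(range(1, 9))


@dataclass(frozen=True)
class Transcript:
    question_id: int
    tokens: tuple

    def __post_init__(self):
        if not 1 <= self.question_id <= 8:
            raise ValueError("question_id must be in 1..8")
        object.__setattr__(self, "tokens", tuple(self.tokens))


@dataclass(frozen=True)
class LinguisticSummary:
    n_positive: int
    n_negative: int
    filler_proportion: float


class SentimentLexicon:
    """word -> polarity ('pos' | 'neg'); no word may carry both."""

    def __init__(self, entries: dict):
        for w, pol in entries.items():
            if pol not in ("pos", "neg"):
                raise ValueError(f"bad polarity {pol!r} for {w!r}")
        self.entries = dict(entries)

    @classmethod
    def from_tsv(cls, path) -> "SentimentLexicon":
        entries = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, pol = line.split("\t")
            if word in entries and entries[word] != pol:
                raise ValueError(f"word {word!r} maps to both polarities")
            entries[word] = pol
        return cls(entries)

    def polarity(self, word: str):
        return self.entries.get(word)


def load_filler_set(path) -> frozenset:
    """One filler word per line; blank lines and # comments ignored."""
    words = [
        w.strip()
        for w in Path(path).read_text(encoding="utf-8").splitlines()
        if w.strip() and not w.startswith("#")
    ]
    return frozenset(words)


# -- tokenizer registry ------------------------------------------------------

_TOKENIZERS: dict[str, Callable[[str], list]] = {}


def register_tokenizer(name: str, fn: Callable[[str], list]) -> None:
    _TOKENIZERS[name] = fn


def _whitespace_lower(text: str) -> list:
    return text.lower().split()


register_tokenizer("whitespace", _whitespace_lower)


def tokenize(text: str, tokenizer_spec: str = "whitespace") -> list:
    """Deterministic token list under the named tokenizer."""
    try:
        fn = _TOKENIZERS[tokenizer_spec]
    except KeyError:
        raise KeyError(f"unknown tokenizer {tokenizer_spec!r}") from None
    return list(fn(text))


# -- feature computations ----------------------------------------------------


def count_sentiment(tokens: Iterable[str], lexicon: SentimentLexicon):
    """Occurrence counts of positive and negative lexicon words (repeats count)."""
    n_pos = n_neg = 0
    for t in tokens:
        pol = lexicon.polarity(t)
        if pol == "pos":
            n_pos += 1
        elif pol == "neg":
            n_neg += 1
    return n_pos, n_neg


def filler_proportion(tokens: Iterable[str], filler_set) -> float:
    """Fraction of tokens that are fillers; empty transcript -> 0.0."""
    tokens = list(tokens)
    if not tokens:
        return 0.0
    return sum(t in filler_set for t in tokens) / len(tokens)


def summarize_session_linguistics(
    transcripts,
    lexicon: SentimentLexicon,
    filler_set,
    sentiment_questions=SENTIMENT_QUESTIONS,
) -> dict:
    """16 named linguistic features for a complete 8-question session.

    Returns an ordered dict ``li.pos.q{k}`` / ``li.neg.q{k}`` for the four
    sentiment questions plus ``li.filler.q{k}`` for all eight.
    """
    sentiment_questions = sorted(sentiment_questions)
    if len(sentiment_questions) != 4:
        raise ValueError("exactly 4 sentiment questions required")
    by_q = {t.question_id: t for t in transcripts}
    missing = [q for q in QUESTION_IDS if q not in by_q]
    if missing:
        raise ValueError(f"missing transcript for question {missing[0]}")
    out = {}
    for q in sentiment_questions:
        n_pos, n_neg = count_sentiment(by_q[q].tokens, lexicon)
        out[f"li.pos.q{q}"] = float(n_pos)
        out[f"li.neg.q{q}"] = float(n_neg)
    for q in QUESTION_IDS:
        out[f"li.filler.q{q}"] = filler_proportion(by_q[q].tokens, filler_set)
    return out
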