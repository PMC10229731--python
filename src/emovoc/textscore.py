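"""Tokenisation and per-participant linguistic features.

Features are computed over the concatenation of a participant's 17
structured-interview responses (optionally per item): raw and
stopword-filtered token counts, distinct types, emotion vs non-emotion
tokens, Emotion Vocabulary (EV: unique emotion words as a percentage of
content words, with emotion words retained in the denominator), the
type/token ratio (TTR), overlapping semantic-category percentages, and
"feel ..." bigrams.

Ratios on empty content are surfaced as ``None`` (missing), never as 0.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lexicon import CategoryDictionary, EmotionLexicon, StopwordList

__all__ = [
    "NUM_ITEMS",
    "Transcript",
    "FeatureVector",
    "FeelBigram",
    "FeelBigramViews",
    "tokenize",
    "compute_features",
    "category_percentages",
    "extract_feel_bigrams",
    "read_transcripts_jsonl",
    "write_transcripts_jsonl",
    "read_transcripts_csv",
    "features_frame",
]

NUM_ITEMS = 17

_TOKEN_RE = re.compile(r"[a-z]+(?:'[a-z]+)*")
_FEEL_FORMS = ("feel", "feels", "feeling")


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens; internal apostrophes are preserved
    (``"I'd run!"`` → ``["i'd", "run"]``); punctuation and digits are
    discarded. Deterministic; empty text yields an empty list."""
    return _TOKEN_RE.findall(text.lower().replace("’", "'"))


@dataclass(frozen=True)
class Transcript:
    """One participant's structured-interview responses.

    ``responses`` maps item id (1..17) to the transcribed response text;
    text may be empty but listed items must be in range.
    """

    participant_id: str
    group: str
    responses: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = [i for i in self.responses if not 1 <= int(i) <= NUM_ITEMS]
        if bad:
            raise ValueError(f"item ids out of 1..{NUM_ITEMS}: {bad}")

    def item_tokens(self, item_id: int) -> list[str]:
        return tokenize(self.responses.get(item_id, ""))

    def all_tokens(self) -> list[str]:
        out: list[str] = []
        for i in sorted(self.responses):
            out.extend(tokenize(self.responses[i]))
        return out


@dataclass(frozen=True)
class FeatureVector:
    """Per-participant (or per-item) linguistic measures.

    Invariants: ``emotion_token_count + non_emotion_word_count ==
    content_word_count`` and ``unique_emotion_word_count <=
    distinct_word_count <= content_word_count <= raw_word_count``; EV and
    TTR are ``None`` when there are no content words.
    """

    participant_id: str
    group: str
    raw_word_count: int
    content_word_count: int
    distinct_word_count: int
    emotion_token_count: int
    unique_emotion_word_count: int
    non_emotion_word_count: int
    ev_percent: float | None
    ttr_percent: float | None
    category_percent: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.emotion_token_count + self.non_emotion_word_count != self.content_word_count:
            raise ValueError("emotion + non-emotion must equal content count")
        if not (
            self.unique_emotion_word_count
            <= self.distinct_word_count
            <= self.content_word_count
            <= self.raw_word_count
        ):
            raise ValueError("count ordering violated")


def _content_tokens(tokens: Sequence[str], stops: StopwordList) -> list[str]:
    return [t for t in tokens if t not in stops]


def compute_features(
    t: Transcript,
    lex: EmotionLexicon,
    stops: StopwordList,
    *,
    per_item: bool = False,
) -> FeatureVector | dict[int, FeatureVector]:
    """Compute the full feature vector for a transcript.

    Counts are over the concatenation of all item responses unless
    ``per_item`` is set, in which case a mapping item id → FeatureVector
    is returned. EV keeps emotion words in its denominator (content word
    count after stopword removal only).
    """
    if len(lex) == 0 or len(stops) == 0:
        raise ValueError("lexicon and stopword list must be nonempty")
    if per_item:
        return {
            i: _features_from_tokens(t.participant_id, t.group, t.item_tokens(i), lex, stops)
            for i in sorted(t.responses)
        }
    return _features_from_tokens(t.participant_id, t.group, t.all_tokens(), lex, stops)


def _features_from_tokens(
    pid: str,
    group: str,
    tokens: Sequence[str],
    lex: EmotionLexicon,
    stops: StopwordList,
) -> FeatureVector:
    content = _content_tokens(tokens, stops)
    n = len(content)
    emo = [tok for tok in content if tok in lex]
    uniq_emo = len(set(emo))
    distinct = len(set(content))
    return FeatureVector(
        participant_id=pid,
        group=group,
        raw_word_count=len(tokens),
        content_word_count=n,
        distinct_word_count=distinct,
        emotion_token_count=len(emo),
        unique_emotion_word_count=uniq_emo,
        non_emotion_word_count=n - len(emo),
        ev_percent=100.0 * uniq_emo / n if n else None,
        ttr_percent=100.0 * distinct / n if n else None,
    )


def category_percentages(
    tokens: Sequence[str], dic: CategoryDictionary
) -> dict[str, float] | None:
    """Percent of tokens matching each dictionary category.

    Categories may overlap (a token can count toward several). Returns
    ``None`` for an empty token list (undefined, not zero).
    """
    if not tokens:
        return None
    counts = {name: 0 for name in dic.names}
    for tok in tokens:
        for name in dic.match(tok):
            counts[name] += 1
    n = len(tokens)
    return {name: 100.0 * c / n for name, c in counts.items()}


@dataclass(frozen=True)
class FeelBigram:
    """A ``feel``/``feels``/``feeling`` + following-token bigram."""

    first: str
    second: str
    item_id: int
    participant_id: str

    def __post_init__(self) -> None:
        if self.first not in _FEEL_FORMS:
            raise ValueError(f"first token must be one of {_FEEL_FORMS}")


@dataclass(frozen=True)
class FeelBigramViews:
    """The three nested bigram filters: all matches, matches whose second
    token is not a stopword, and the residual "feel —" constructions whose
    second token is also not in the emotion lexicon."""

    all: tuple[FeelBigram, ...]
    stop_filtered: tuple[FeelBigram, ...]
    residual: tuple[FeelBigram, ...]


def extract_feel_bigrams(
    t: Transcript,
    stops: StopwordList,
    lex: EmotionLexicon,
) -> FeelBigramViews:
    """Bigrams with first token in {feel, feels, feeling}, per response.

    Bigrams never span item boundaries. The stop-filtered view drops
    bigrams whose second token is a stopword; the residual view further
    drops those whose second token is an emotion-lexicon term.
    """
    found: list[FeelBigram] = []
    for item_id in sorted(t.responses):
        toks = t.item_tokens(item_id)
        for first, second in zip(toks, toks[1:]):
            if first in _FEEL_FORMS:
                found.append(
                    FeelBigram(first=first, second=second, item_id=item_id, participant_id=t.participant_id)
                )
    stop_filtered = tuple(b for b in found if b.second not in stops)
    residual = tuple(b for b in stop_filtered if b.second not in lex)
    return FeelBigramViews(all=tuple(found), stop_filtered=stop_filtered, residual=residual)


# ---------------------------------------------------------------------------
# Readers / writers


def read_transcripts_jsonl(path: str | Path) -> list[Transcript]:
    """Read transcripts from JSONL: one participant per line with keys
    ``participant_id``, ``group``, ``responses`` (item → text)."""
    out: list[Transcript] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            try:
                responses = {int(k): str(v) for k, v in rec["responses"].items()}
                out.append(
                    Transcript(
                        participant_id=str(rec["participant_id"]),
                        group=str(rec["group"]),
                        responses=responses,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid transcript record: {exc}") from exc
    return out


def write_transcripts_jsonl(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts in the JSONL dialect read by
    :func:`read_transcripts_jsonl` (canonical key order: byte-stable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in transcripts:
            rec = {
                "participant_id": t.participant_id,
                "group": t.group,
                "responses": {str(i): t.responses[i] for i in sorted(t.responses)},
            }
            fh.write(json.dumps(rec, sort_keys=True, separators=(",", ":")) + "\n")


def read_transcripts_csv(path: str | Path) -> list[Transcript]:
    """Read long-format CSV transcripts with columns ``participant_id``,
    ``group``, ``item_id``, ``response_text``."""
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    required = {"participant_id", "group", "item_id", "response_text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[Transcript] = []
    for (pid, group), sub in df.groupby(["participant_id", "group"], sort=True):
        responses = {
            int(r.item_id): ("" if pd.isna(r.response_text) else str(r.response_text))
            for r in sub.itertuples()
        }
        out.append(Transcript(participant_id=pid, group=group, responses=responses))
    return out


def features_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """Tidy one-row-per-participant feature table."""
    rows = []
    for f in features:
        row: dict[str, object] = {
            "participant_id": f.participant_id,
            "group": f.group,
            "raw_word_count": f.raw_word_count,
            "content_word_count": f.content_word_count,
            "distinct_word_count": f.distinct_word_count,
            "emotion_token_count": f.emotion_token_count,
            "unique_emotion_word_count": f.unique_emotion_word_count,
            "non_emotion_word_count": f.non_emotion_word_count,
            "ev_percent": f.ev_percent,
            "ttr_percent": f.ttr_percent,
        }
        if f.category_percent:
            for name, pct in f.category_percent.items():
                row[f"pct_{name}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
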