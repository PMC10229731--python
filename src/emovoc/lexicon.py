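"""Affect lexicon, category dictionary and stopword handling.

The emotion lexicon is an exact-match set of affective-state terms
(adjectival bases plus their syntactic variants, e.g. ``angry`` →
``anger``, ``angrily``), each assigned to one of the coarse affect
categories used throughout the analysis: ``anger``, ``anxiety``,
``sadness``, ``positive`` and ``other_affect``.

The category dictionary is a wildcard-capable word-category table in the
classic ``.dic`` dialect (header block of ``id<TAB>name`` rows delimited
by ``%`` lines, then ``pattern<TAB>id...`` rows) used to compute the
percentage of tokens falling in overlapping semantic categories such as
*affect*, *posemo*, *negemo*, *anger*, *anxiety*, *sadness*.

The packaged lexicon is a compact fallback (~65 base terms plus
variants), not the full published 248-term affective taxonomy, and is a
configurable input everywhere it is consumed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "EmotionLexicon",
    "CategoryDictionary",
    "StopwordList",
    "load_emotion_lexicon",
    "load_category_dictionary",
    "match_categories",
    "build_stopwords",
    "default_emotion_lexicon",
    "default_category_dictionary",
    "default_stopwords",
    "CATEGORIES",
]

CATEGORIES = ("anger", "anxiety", "sadness", "positive", "other_affect")


def _data_text(name: str) -> str:
    return resources.files("emovoc.data").joinpath(name).read_text(encoding="utf-8")


@dataclass(frozen=True)
class EmotionLexicon:
    """Exact-match affect-term set with a variant map and category labels.

    ``terms`` holds every matchable token (bases and variants, all
    lowercase single tokens); ``base_to_variants`` maps each base term to
    its listed variants; ``category_of`` assigns every term a category
    (``other_affect`` when unstated).
    """

    terms: frozenset[str]
    base_to_variants: Mapping[str, tuple[str, ...]]
    category_of: Mapping[str, str]

    def __post_init__(self) -> None:
        for t in self.terms:
            if t != t.lower() or not t or any(c.isspace() for c in t):
                raise ValueError(f"lexicon terms must be lowercase single tokens: {t!r}")
        missing = self.terms - set(self.category_of)
        if missing:
            raise ValueError(f"category_of undefined for {sorted(missing)[:5]}")

    def __contains__(self, token: str) -> bool:
        return token in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def base_of(self, term: str) -> str:
        """Return the base form a term maps to (identity for base terms)."""
        if term in self.base_to_variants:
            return term
        for base, variants in self.base_to_variants.items():
            if term in variants:
                return base
        raise KeyError(term)

    def sublexicon(self, category: str) -> frozenset[str]:
        """All terms (bases and variants) labelled with ``category``."""
        return frozenset(t for t in self.terms if self.category_of[t] == category)

    def to_tsv(self, path: str | Path) -> None:
        """Write the lexicon back out in the TSV input dialect."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["term", "variants", "category"])
            for base in sorted(self.base_to_variants):
                w.writerow(
                    [
                        base,
                        ",".join(self.base_to_variants[base]),
                        self.category_of[base],
                    ]
                )


def load_emotion_lexicon(source: str | Path | io.TextIOBase) -> EmotionLexicon:
    """Load an :class:`EmotionLexicon` from a TSV table.

    Columns: ``term`` (required base term), ``variants`` (optional,
    comma-separated), ``category`` (optional; defaults to
    ``other_affect``). Duplicate base terms and entries containing
    whitespace are rejected with the offending row numbers.
    """
    if isinstance(source, (str, Path)):
        fh: io.TextIOBase = open(source, encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "term" not in reader.fieldnames:
            raise ValueError("lexicon TSV must have a 'term' column")
        bases: dict[str, tuple[str, ...]] = {}
        category_of: dict[str, str] = {}
        dup_rows: list[int] = []
        for rownum, row in enumerate(reader, start=2):
            base = (row.get("term") or "").strip().lower()
            if not base:
                continue
            if any(c.isspace() for c in base):
                raise ValueError(f"row {rownum}: term {base!r} is not a single token")
            if base in bases:
                dup_rows.append(rownum)
                continue
            raw_variants = (row.get("variants") or "").strip()
            variants = tuple(
                v.strip().lower() for v in raw_variants.split(",") if v.strip()
            )
            for v in variants:
                if any(c.isspace() for c in v):
                    raise ValueError(f"row {rownum}: variant {v!r} is not a single token")
            category = (row.get("category") or "").strip().lower() or "other_affect"
            bases[base] = variants
            category_of[base] = category
            for v in variants:
                category_of.setdefault(v, category)
        if dup_rows:
            raise ValueError(f"duplicate base terms at rows {dup_rows}")
    finally:
        if close:
            fh.close()
    terms = frozenset(category_of)
    return EmotionLexicon(terms=terms, base_to_variants=bases, category_of=category_of)


@dataclass(frozen=True)
class CategoryDictionary:
    """Ordered pattern table mapping tokens to overlapping categories.

    A pattern is either a literal token or a prefix ending in ``*``; each
    pattern carries a set of category ids defined in ``category_names``.
    """

    patterns: tuple[tuple[str, frozenset[int]], ...]
    category_names: Mapping[int, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pat, ids in self.patterns:
            if pat in seen:
                raise ValueError(f"duplicate pattern {pat!r}")
            seen.add(pat)
            unknown = ids - set(self.category_names)
            if unknown:
                raise ValueError(f"pattern {pat!r} references unknown ids {sorted(unknown)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.category_names[i] for i in sorted(self.category_names))

    def match(self, token: str) -> set[str]:
        return {self.category_names[i] for i in match_categories(token, self)}


def load_category_dictionary(dic_text: str) -> CategoryDictionary:
    """Parse a ``.dic``-dialect category dictionary from text.

    The header block is delimited by lines containing only ``%`` and holds
    ``id<TAB>name`` rows; the body holds ``pattern<TAB>id[<TAB>id...]``
    rows. Prefix wildcards (``hate*``) are preserved verbatim.
    """
    lines = dic_text.splitlines()
    delims = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delims) < 2:
        raise ValueError(".dic header must be delimited by two '%' lines")
    header, body = lines[delims[0] + 1 : delims[1]], lines[delims[1] + 1 :]
    category_names: dict[int, str] = {}
    for ln in header:
        if not ln.strip():
            continue
        parts = ln.split()
        cid, name = int(parts[0]), parts[1]
        category_names[cid] = name
    patterns: list[tuple[str, frozenset[int]]] = []
    for ln in body:
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = ln.split()
        pat = parts[0].lower()
        ids = frozenset(int(p) for p in parts[1:])
        if not ids:
            raise ValueError(f"pattern {pat!r} lists no category ids")
        patterns.append((pat, ids))
    return CategoryDictionary(patterns=tuple(patterns), category_names=category_names)


def match_categories(token: str, dic: CategoryDictionary) -> set[int]:
    """Category ids of every pattern matching ``token``.

    Literal patterns require equality; a wildcard pattern ``abc*`` matches
    any token with prefix ``abc``. No match yields the empty set.
    """
    if not token:
        raise ValueError("token must be nonempty")
    out: set[int] = set()
    for pat, ids in dic.patterns:
        if pat.endswith("*"):
            if token.startswith(pat[:-1]):
                out |= ids
        elif token == pat:
            out |= ids
    return out


@dataclass(frozen=True)
class StopwordList:
    """Lowercase stopword set, including transcription filler sounds."""

    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("stopword list must be nonempty")
        bad = [w for w in self.words if w != w.lower()]
        if bad:
            raise ValueError(f"stopwords must be lowercase: {bad[:5]}")

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


def build_stopwords(base_list: Iterable[str], custom_fillers: Iterable[str] = ()) -> StopwordList:
    """Union of a base stopword list and custom fillers, lowercased."""
    words = {w.strip().lower() for w in base_list if w.strip()}
    words |= {w.strip().lower() for w in custom_fillers if w.strip()}
    return StopwordList(words=frozenset(words))


DEFAULT_FILLERS = ("hmm", "ahm", "ehm")


def default_emotion_lexicon() -> EmotionLexicon:
    """The packaged fallback mini-lexicon (≈65 bases plus variants)."""
    return load_emotion_lexicon(io.StringIO(_data_text("emotion_lexicon.tsv")))


def default_category_dictionary() -> CategoryDictionary:
    """The packaged open affect category dictionary."""
    return load_category_dictionary(_data_text("affect_categories.dic"))


def default_stopwords() -> StopwordList:
    """Packaged English function-word list plus transcription fillers."""
    words = [
        ln.strip()
        for ln in _data_text("stopwords.txt").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return build_stopwords(words, DEFAULT_FILLERS)
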