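"""Provocation-congruence analysis.

Each structured-interview item is designed to provoke a particular
emotion: six anger items (2, 3, 5, 6, 9, 10), four fear/anxiety items
(4, 8, 14, 15) and one loss/sadness item (13); the remainder (including
the two compliment items, which are not identified by number) are
unclassified and excluded from testing. For every response we measure
the percentage of tokens in the emotion category *congruent* with the
item's provocation, and, for the incongruence analysis, the off-diagonal
category percentages. The unit of analysis is the individual item
response pooled across participants (participant-level aggregation is
available as an option); groups are compared with Welch's t and Cohen's
d (ASD − NT ordering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .lexicon import CategoryDictionary, StopwordList
from .stats import cohen_d, welch_t
from .textscore import NUM_ITEMS, Transcript

__all__ = [
    "ProvocationMap",
    "default_provocation_map",
    "congruent_percent",
    "response_percent_table",
    "congruence_table",
    "incongruence_tests",
    "TESTED_PROVOCATIONS",
]

TESTED_PROVOCATIONS = ("anger", "anxiety", "sadness")

_DEFAULT_ITEMS: dict[str, frozenset[int]] = {
    "anger": frozenset({2, 3, 5, 6, 9, 10}),
    "anxiety": frozenset({4, 8, 14, 15}),
    "sadness": frozenset({13}),
}


@dataclass(frozen=True)
class ProvocationMap:
    """Item → provocation category map over all 17 items."""

    item_to_category: Mapping[int, str]

    def __post_init__(self) -> None:
        if set(self.item_to_category) != set(range(1, NUM_ITEMS + 1)):
            raise ValueError(f"map must cover exactly items 1..{NUM_ITEMS}")

    def items_for(self, category: str) -> list[int]:
        return sorted(i for i, c in self.item_to_category.items() if c == category)


def default_provocation_map() -> ProvocationMap:
    mapping = {i: "unclassified" for i in range(1, NUM_ITEMS + 1)}
    for cat, items in _DEFAULT_ITEMS.items():
        for i in items:
            mapping[i] = cat
    return ProvocationMap(item_to_category=mapping)


def congruent_percent(
    tokens: Sequence[str], provocation: str, dic: CategoryDictionary
) -> float | None:
    """Percent of response tokens in the emotion category matching the
    provocation; ``None`` (missing) for an empty response."""
    if provocation not in TESTED_PROVOCATIONS:
        raise ValueError(f"provocation must be one of {TESTED_PROVOCATIONS}")
    if not tokens:
        return None
    hits = sum(1 for tok in tokens if provocation in dic.match(tok))
    return 100.0 * hits / len(tokens)


def response_percent_table(
    cohort: Sequence[Transcript],
    pmap: ProvocationMap,
    dic: CategoryDictionary,
    stops: StopwordList | None = None,
) -> pd.DataFrame:
    """Long table of per-response emotion-category percentages.

    One row per non-empty (participant, item) response on a tested
    provocation item, with columns for each tested word category. Token
    basis is the raw response tokens unless a stopword list is supplied.
    """
    rows = []
    for t in cohort:
        for item_id in sorted(t.responses):
            prov = pmap.item_to_category[item_id]
            if prov not in TESTED_PROVOCATIONS:
                continue
            toks = t.item_tokens(item_id)
            if stops is not None:
                toks = [tok for tok in toks if tok not in stops]
            if not toks:
                continue
            n = len(toks)
            counts = dict.fromkeys(TESTED_PROVOCATIONS, 0)
            for tok in toks:
                for cat in dic.match(tok):
                    if cat in counts:
                        counts[cat] += 1
            row = {
                "participant_id": t.participant_id,
                "group": t.group,
                "item_id": item_id,
                "provocation": prov,
            }
            row.update({f"pct_{c}": 100.0 * k / n for c, k in counts.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def _welch_row(
    prov: str, word_cat: str, sub: pd.DataFrame, groups: tuple[str, str]
) -> dict | None:
    ga, gb = groups
    col = f"pct_{word_cat}"
    xa = sub.loc[sub["group"] == ga, col].to_numpy(dtype=float)
    xb = sub.loc[sub["group"] == gb, col].to_numpy(dtype=float)
    row = {
        "provocation": prov,
        "word_category": word_cat,
        f"{ga}_mean": float(np.mean(xa)) if xa.size else np.nan,
        f"{ga}_sd": float(np.std(xa, ddof=1)) if xa.size > 1 else np.nan,
        f"{gb}_mean": float(np.mean(xb)) if xb.size else np.nan,
        f"{gb}_sd": float(np.std(xb, ddof=1)) if xb.size > 1 else np.nan,
        f"n_{ga}": int(xa.size),
        f"n_{gb}": int(xb.size),
    }
    if xa.size < 2 or xb.size < 2:
        warnings.warn(
            f"{prov}/{word_cat}: fewer than 2 responses in a group, test skipped"
        )
        row.update({"t": np.nan, "df": np.nan, "p": np.nan, "d": np.nan})
        return row
    if np.var(xa) == 0 and np.var(xb) == 0 and np.mean(xa) == np.mean(xb):
        warnings.warn(f"{prov}/{word_cat}: degenerate all-equal data, test skipped")
        row.update({"t": np.nan, "df": np.nan, "p": np.nan, "d": np.nan})
        return row
    t, df, p = welch_t(xa, xb)
    row.update({"t": t, "df": df, "p": p, "d": cohen_d(xa, xb)})
    return row


def congruence_table(
    cohort: Sequence[Transcript],
    pmap: ProvocationMap,
    dic: CategoryDictionary,
    *,
    groups: tuple[str, str] = ("ASD", "NT"),
    stops: StopwordList | None = None,
    per_participant: bool = False,
) -> pd.DataFrame:
    """Congruent emotion-word use by provocation type, compared across
    groups with Welch's t and Cohen's d (first group minus second).

    One row per tested provocation, for the word category matching it.
    With ``per_participant`` the response-level percentages are averaged
    within participant before testing.
    """
    table = response_percent_table(cohort, pmap, dic, stops)
    if table.empty:
        raise ValueError("no scorable responses on tested provocation items")
    if per_participant:
        table = (
            table.groupby(["participant_id", "group", "provocation"], as_index=False)
            .mean(numeric_only=True)
        )
    rows = []
    for prov in TESTED_PROVOCATIONS:
        sub = table[table["provocation"] == prov]
        if sub.empty:
            continue
        row = _welch_row(prov, prov, sub, groups)
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows)


def incongruence_tests(
    cohort: Sequence[Transcript],
    pmap: ProvocationMap,
    dic: CategoryDictionary,
    *,
    groups: tuple[str, str] = ("ASD", "NT"),
    stops: StopwordList | None = None,
    per_participant: bool = False,
) -> pd.DataFrame:
    """Welch tests for the six off-diagonal (provocation, word category)
    pairs — e.g. anger words in response to anxiety provocations."""
    table = response_percent_table(cohort, pmap, dic, stops)
    if table.empty:
        raise ValueError("no scorable responses on tested provocation items")
    if per_participant:
        table = (
            table.groupby(["participant_id", "group", "provocation"], as_index=False)
            .mean(numeric_only=True)
        )
    rows = []
    for prov in TESTED_PROVOCATIONS:
        sub = table[table["provocation"] == prov]
        if sub.empty:
            continue
        for word_cat in TESTED_PROVOCATIONS:
            if word_cat == prov:
                continue
            row = _welch_row(prov, word_cat, sub, groups)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows)
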