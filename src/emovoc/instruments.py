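"""Questionnaire scoring: TAS-20, AQ-10 and the automated APRQ rating.

TAS-20: twenty 5-point Likert items; reverse-keyed items are transformed
v → 6 − v before summing; totals of 61 or more fall in the conventional
alexithymic range. AQ-10: ten 4-point Likert items collapsed to a 0/1
bimodal score per item (a point when the response falls on the keyed
side); six or more screens positive. The APRQ auto-scorer is a
lexicon-based approximation of the human 0/1 rating: an item scores 1
iff the response contains at least one emotion-lexicon token. Human
raters additionally treat physical-sensation and pure situation
descriptions as alexithymic, which a lexicon-only rule cannot see — a
documented validity caveat, not a bug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import EmotionLexicon, StopwordList
from .textscore import NUM_ITEMS, Transcript, tokenize

__all__ = [
    "TAS20_REVERSE_ITEMS",
    "AQ10_AGREE_KEYED",
    "TAS20_CUTOFF",
    "AQ10_CUTOFF",
    "InstrumentScores",
    "score_tas20",
    "score_aq10",
    "auto_score_aprq",
    "cronbach_alpha",
    "group_proportion_summary",
    "round_half_even",
    "score_instruments_table",
]

# Published standard keys; both are configuration, not constants of the code.
TAS20_REVERSE_ITEMS = frozenset({4, 5, 10, 18, 19})
AQ10_AGREE_KEYED = frozenset({1, 7, 8, 10})

TAS20_CUTOFF = 61
AQ10_CUTOFF = 6


@dataclass(frozen=True)
class InstrumentScores:
    """Scored totals and screening flags for one participant."""

    participant_id: str
    tas20_total: int | None
    tas20_alexithymic: bool | None
    aq10_total: int | None
    aq10_screen_positive: bool | None
    aprq_total: int | None = None


def score_tas20(
    items: Sequence[int], reverse_items: frozenset[int] = TAS20_REVERSE_ITEMS
) -> int:
    """Sum of 20 Likert-5 items with reverse-keyed items mapped v → 6 − v.

    Raises ``ValueError`` on a wrong item count or out-of-range values;
    callers scoring tables treat that as instrument-missing, not imputed.
    """
    if len(items) != 20:
        raise ValueError(f"TAS-20 requires 20 items, got {len(items)}")
    total = 0
    for idx, v in enumerate(items, start=1):
        v = int(v)
        if not 1 <= v <= 5:
            raise ValueError(f"TAS-20 item {idx} out of range 1..5: {v}")
        total += (6 - v) if idx in reverse_items else v
    return total


def score_aq10(
    items: Sequence[int], agree_keyed: frozenset[int] = AQ10_AGREE_KEYED
) -> int:
    """Bimodal AQ-10 total: a point when the response falls on the keyed
    side (agree side = Likert 1/2 for agree-keyed items, disagree side =
    3/4 otherwise)."""
    if len(items) != 10:
        raise ValueError(f"AQ-10 requires 10 items, got {len(items)}")
    total = 0
    for idx, v in enumerate(items, start=1):
        v = int(v)
        if not 1 <= v <= 4:
            raise ValueError(f"AQ-10 item {idx} out of range 1..4: {v}")
        agree_side = v <= 2
        keyed_agree = idx in agree_keyed
        total += int(agree_side == keyed_agree)
    return total


def auto_score_aprq(
    t: Transcript,
    lex: EmotionLexicon,
    stops: StopwordList | None = None,
) -> tuple[int, dict[int, int]]:
    """Automated APRQ rating: item scores 1 iff at least one (content)
    token of the response is an emotion-lexicon term.

    Returns ``(total, per_item)`` over all 17 items; missing items score 0
    with a warning.
    """
    if not t.responses:
        raise ValueError("transcript has no items")
    per_item: dict[int, int] = {}
    missing = [i for i in range(1, NUM_ITEMS + 1) if i not in t.responses]
    if missing:
        warnings.warn(
            f"participant {t.participant_id}: items {missing} missing, scored 0",
            stacklevel=2,
        )
    for i in range(1, NUM_ITEMS + 1):
        toks = tokenize(t.responses.get(i, ""))
        if stops is not None:
            toks = [tok for tok in toks if tok not in stops]
        per_item[i] = int(any(tok in lex for tok in toks))
    return sum(per_item.values()), per_item


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's α = k/(k−1) · (1 − Σ item variances / total variance).

    Sample variances (ddof=1). Returns ``nan`` when the totals have zero
    variance (undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    if np.isnan(x).any():
        raise ValueError("missing cells not allowed")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return k / (k - 1) * (1.0 - item_var / total_var)


def round_half_even(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-to-even at ``ndigits`` (reporting convention:
    15.625 → 15.6, 56.25 → 56.2)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def group_proportion_summary(flags: Iterable[bool], ndigits: int = 1) -> tuple[int, float]:
    """(count flagged, percent of the group) with the percent computed
    exactly and rounded half-to-even at the printed precision."""
    flags = [bool(f) for f in flags]
    if not flags:
        raise ValueError("empty group")
    count = sum(flags)
    pct = Decimal(100 * count) / Decimal(len(flags))
    q = Decimal(1).scaleb(-ndigits)
    return count, float(pct.quantize(q, rounding=ROUND_HALF_EVEN))


def score_instruments_table(
    df: pd.DataFrame,
    *,
    reverse_items: frozenset[int] = TAS20_REVERSE_ITEMS,
    agree_keyed: frozenset[int] = AQ10_AGREE_KEYED,
) -> pd.DataFrame:
    """Score a one-row-per-participant instrument CSV table.

    Expects columns ``participant_id``, ``tas_1..tas_20``, ``aq_1..aq_10``
    (missing cells empty). A participant with any missing or out-of-range
    item has that instrument marked missing (NaN totals), never imputed.
    """
    tas_cols = [f"tas_{i}" for i in range(1, 21)]
    aq_cols = [f"aq_{i}" for i in range(1, 11)]
    rows = []
    for rec in df.itertuples():
        row: dict[str, object] = {"participant_id": getattr(rec, "participant_id")}
        tas_vals = [getattr(rec, c, np.nan) for c in tas_cols]
        try:
            if any(pd.isna(v) for v in tas_vals):
                raise ValueError("missing")
            total = score_tas20([int(v) for v in tas_vals], reverse_items)
            row["tas20_total"] = total
            row["tas20_alexithymic"] = total >= TAS20_CUTOFF
        except ValueError:
            row["tas20_total"] = np.nan
            row["tas20_alexithymic"] = np.nan
        aq_vals = [getattr(rec, c, np.nan) for c in aq_cols]
        try:
            if any(pd.isna(v) for v in aq_vals):
                raise ValueError("missing")
            total = score_aq10([int(v) for v in aq_vals], agree_keyed)
            row["aq10_total"] = total
            row["aq10_screen_positive"] = total >= AQ10_CUTOFF
        except ValueError:
            row["aq10_total"] = np.nan
            row["aq10_screen_positive"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
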