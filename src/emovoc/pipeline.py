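"""End-to-end analysis: lexicon → features → congruence → statistics.

``run_full_analysis`` assembles the full report for a cohort: the
per-participant feature table; two-group comparisons (rank-sum W with
Vargha–Delaney A) for word counts, emotion counts, EV, TTR and the
semantic-category percentages; the Spearman correlation matrix over
EV/TTR/emotion count/APRQ/age/TAS-20/AQ-10 with the partial AQ-10–EV
correlation controlling for TTR; the congruence and incongruence tables;
the two nested logistic models of group membership (TAS-20 only, and
TAS-20 + emotion and non-emotion word counts) with their diagnostics;
and the feel-bigram summary. Deterministic given its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import congruence as cong
from . import stats as st
from .instruments import auto_score_aprq, score_instruments_table
from .lexicon import (
    CategoryDictionary,
    EmotionLexicon,
    StopwordList,
    default_category_dictionary,
    default_emotion_lexicon,
    default_stopwords,
)
from .textscore import (
    Transcript,
    category_percentages,
    compute_features,
    extract_feel_bigrams,
    features_frame,
)

logger = logging.getLogger("emovoc")

__all__ = ["AnalysisReport", "run_full_analysis", "score_cohort"]

#: measures compared between groups with the rank-sum test
GROUP_MEASURES = (
    "raw_word_count",
    "content_word_count",
    "distinct_word_count",
    "emotion_token_count",
    "non_emotion_word_count",
    "ev_percent",
    "ttr_percent",
    "pct_affect",
    "pct_posemo",
    "pct_negemo",
)

CORRELATION_VARS = (
    "ev_percent",
    "ttr_percent",
    "emotion_token_count",
    "aprq_total",
    "age",
    "tas20_total",
    "aq10_total",
)


@dataclass
class AnalysisReport:
    """Full analysis output; every table is traceable to the cohort hash."""

    features: pd.DataFrame
    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame
    partial_aq10_ev_given_ttr: tuple[float, float]
    congruence: pd.DataFrame
    incongruence: pd.DataFrame
    logistic_tas: st.LogisticFit | None
    logistic_full: st.LogisticFit | None
    diagnostics: dict
    bigram_summary: dict
    metadata: dict

    def save(self, directory: str | Path) -> None:
        """Write the report as CSV tables plus a JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(directory / "features.csv", index=False)
        self.group_tests.to_csv(directory / "group_tests.csv", index=False)
        self.correlations.to_csv(directory / "correlations.csv")
        self.correlation_p.to_csv(directory / "correlation_p.csv")
        self.congruence.to_csv(directory / "congruence.csv", index=False)
        self.incongruence.to_csv(directory / "incongruence.csv", index=False)
        summary: dict = {
            "metadata": self.metadata,
            "bigram_summary": self.bigram_summary,
            "partial_aq10_ev_given_ttr": list(self.partial_aq10_ev_given_ttr),
            "diagnostics": _jsonify(self.diagnostics),
        }
        for name, fit in (("tas_model", self.logistic_tas), ("full_model", self.logistic_full)):
            if fit is None:
                summary[name] = None
                continue
            summary[name] = {
                "coefficients": fit.summary().to_dict(orient="index"),
                "n": fit.n_obs,
                "aic": fit.aic,
                "model_chi2": fit.model_chi2,
                "model_df": fit.model_df,
                "model_p": fit.model_p,
                "r2_cox_snell": fit.r2_cox_snell,
                "r2_nagelkerke": fit.r2_nagelkerke,
                "classification_rate": fit.classification_rate,
                "baseline_rate": fit.baseline_rate,
            }
        with open(directory / "report.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _cohort_hash(transcripts: Sequence[Transcript]) -> str:
    h = hashlib.sha256()
    for t in sorted(transcripts, key=lambda t: t.participant_id):
        h.update(t.participant_id.encode())
        h.update(t.group.encode())
        for i in sorted(t.responses):
            h.update(f"{i}:{t.responses[i]}".encode())
    return h.hexdigest()


def score_cohort(
    transcripts: Sequence[Transcript],
    lex: EmotionLexicon,
    stops: StopwordList,
    dic: CategoryDictionary | None = None,
) -> pd.DataFrame:
    """Per-participant feature table (with category percentages when a
    dictionary is given) plus the automated APRQ total."""
    feats = []
    aprq = {}
    for t in transcripts:
        fv = compute_features(t, lex, stops)
        if dic is not None:
            content = [tok for tok in t.all_tokens() if tok not in stops]
            pct = category_percentages(content, dic)
            fv = type(fv)(**{**fv.__dict__, "category_percent": pct})
        feats.append(fv)
        aprq[t.participant_id], _ = auto_score_aprq(t, lex)
    df = features_frame(feats)
    df["aprq_total"] = df["participant_id"].map(aprq)
    return df


def run_full_analysis(
    transcripts: Sequence[Transcript],
    instruments: pd.DataFrame,
    *,
    lex: EmotionLexicon | None = None,
    dic: CategoryDictionary | None = None,
    stops: StopwordList | None = None,
    groups: tuple[str, str] = ("ASD", "NT"),
) -> AnalysisReport:
    """Run the complete analysis for a cohort.

    ``instruments`` is a one-row-per-participant table with
    ``participant_id``, optional ``age``, ``tas_1..tas_20`` and
    ``aq_1..aq_10`` columns. Participants missing the TAS-20 are dropped
    from the logistic models (with a logged count), mirroring ordinary
    incomplete-questionnaire handling.
    """
    lex = lex or default_emotion_lexicon()
    dic = dic or default_category_dictionary()
    stops = stops or default_stopwords()
    logger.info(
        "analysis start: %d transcripts, lexicon %d terms, %d stopwords",
        len(transcripts), len(lex), len(stops),
    )

    features = score_cohort(transcripts, lex, stops, dic)
    scored = score_instruments_table(instruments)
    merged = features.merge(scored, on="participant_id", how="left")
    if "age" in instruments.columns:
        merged = merged.merge(
            instruments[["participant_id", "age"]], on="participant_id", how="left"
        )

    ga, gb = groups
    rows = []
    for measure in GROUP_MEASURES:
        if measure not in merged.columns:
            continue
        xa = merged.loc[merged["group"] == ga, measure].dropna().to_numpy(float)
        xb = merged.loc[merged["group"] == gb, measure].dropna().to_numpy(float)
        if xa.size < 2 or xb.size < 2:
            continue
        comp = st.compare_groups(xa, xb, method="wilcoxon")
        rows.append(
            {
                "measure": measure,
                f"{ga}_mean": xa.mean(),
                f"{ga}_sd": xa.std(ddof=1),
                f"{gb}_mean": xb.mean(),
                f"{gb}_sd": xb.std(ddof=1),
                "W": comp.statistic,
                "p": comp.p_value,
                "A": comp.effect_size,
                "interpretation": comp.interpretation,
            }
        )
    group_tests = pd.DataFrame(rows)

    corr_vars = [v for v in CORRELATION_VARS if v in merged.columns]
    k = len(corr_vars)
    rho_m = pd.DataFrame(np.eye(k), index=corr_vars, columns=corr_vars)
    p_m = pd.DataFrame(np.zeros((k, k)), index=corr_vars, columns=corr_vars)
    for i, vi in enumerate(corr_vars):
        for j2 in range(i + 1, k):
            vj = corr_vars[j2]
            sub = merged[[vi, vj]].dropna()
            if len(sub) < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = st.spearman(sub[vi], sub[vj])
            rho_m.iloc[i, j2] = rho_m.iloc[j2, i] = rho
            p_m.iloc[i, j2] = p_m.iloc[j2, i] = p

    sub = merged[["aq10_total", "ev_percent", "ttr_percent"]].dropna()
    if len(sub) >= 4:
        partial = st.partial_spearman(sub["aq10_total"], sub["ev_percent"], sub["ttr_percent"])
    else:
        partial = (float("nan"), float("nan"))

    pmap = cong.default_provocation_map()
    congruence_table = cong.congruence_table(transcripts, pmap, dic, groups=groups)
    incongruence = cong.incongruence_tests(transcripts, pmap, dic, groups=groups)

    model_df = merged.dropna(subset=["tas20_total"]).reset_index(drop=True)
    dropped = len(merged) - len(model_df)
    if dropped:
        logger.info("logistic models: dropped %d participants missing TAS-20", dropped)
    logistic_tas = logistic_full = None
    diagnostics: dict = {"n_model": len(model_df), "n_dropped_missing_tas": dropped}
    if model_df["group"].nunique() == 2 and len(model_df) >= 10:
        y = (model_df["group"] == ga).astype(int).to_numpy()
        try:
            logistic_tas = st.logistic_fit(model_df[["tas20_total"]], y)
            X_full = model_df[["tas20_total", "emotion_token_count", "non_emotion_word_count"]]
            logistic_full = st.logistic_fit(X_full, y)
            hl = st.hosmer_lemeshow(logistic_full)
            diagnostics["hosmer_lemeshow"] = {"chi2": hl[0], "df": hl[1], "p": hl[2]}
            diagnostics["vif"] = st.vif(X_full)
            diagnostics["max_cooks_distance"] = float(
                np.max(st.cooks_distance(logistic_full))
            )
            diagnostics["box_tidwell_p"] = st.box_tidwell(
                X_full, y, list(X_full.columns), shift=True
            )
        except st.SeparationError as exc:
            logger.warning("logistic fit aborted: %s", exc)
            diagnostics["separation"] = str(exc)

    big_all: Counter = Counter()
    n_all = n_stop = n_resid = 0
    for t in transcripts:
        views = extract_feel_bigrams(t, stops, lex)
        n_all += len(views.all)
        n_stop += len(views.stop_filtered)
        n_resid += len(views.residual)
        big_all.update((b.first, b.second) for b in views.all)
    bigram_summary = {
        "n_total": n_all,
        "n_after_stopword_filter": n_stop,
        "n_residual_non_emotion": n_resid,
        "most_common": [
            {"bigram": f"{a} {b}", "count": c} for (a, b), c in big_all.most_common(5)
        ],
    }

    metadata = {
        "cohort_hash": _cohort_hash(transcripts),
        "n_participants": len(transcripts),
        "lexicon_size": len(lex),
        "stopword_size": len(stops),
        "groups": list(groups),
    }
    return AnalysisReport(
        features=merged,
        group_tests=group_tests,
        correlations=rho_m,
        correlation_p=p_m,
        partial_aq10_ev_given_ttr=partial,
        congruence=congruence_table,
        incongruence=incongruence,
        logistic_tas=logistic_tas,
        logistic_full=logistic_full,
        diagnostics=diagnostics,
        bigram_summary=bigram_summary,
        metadata=metadata,
    )
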