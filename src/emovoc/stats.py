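"""Statistical battery: rank-sum tests with Vargha–Delaney A, Welch t and
Cohen's d, Spearman and partial Spearman correlation, chi-square, and
binary logistic regression with its diagnostic suite (pseudo-R²,
Hosmer–Lemeshow, Box–Tidwell, VIF, Cook's distance).

Conventions: two-sided p-values throughout; Vargha–Delaney ties credited
0.5; the rank-sum statistic W is the Mann–Whitney U of the first sample
(the R ``wilcox.test`` convention), so A = W / (n_x · n_y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "GroupComparison",
    "LogisticFit",
    "SeparationError",
    "wilcoxon_rank_sum",
    "vda_effect_size",
    "interpret_vda",
    "interpret_cohen_d",
    "spearman",
    "partial_spearman",
    "welch_t",
    "cohen_d",
    "chi_square_independence",
    "logistic_fit",
    "hosmer_lemeshow",
    "box_tidwell",
    "vif",
    "cooks_distance",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """A two-group test result with its effect size and interpretation."""

    statistic_name: str
    statistic: float
    p_value: float
    effect_size_name: str
    effect_size: float
    interpretation: str
    df: float | None = None


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


# ---------------------------------------------------------------------------
# Nonparametric comparisons


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], *, exact: bool | None = None
) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (W, p) with W the Mann–Whitney U
    of ``x``.

    The p-value is exact (full enumeration of rank assignments) when both
    samples have n ≤ 10 and there are no ties, unless overridden with
    ``exact``; otherwise the normal approximation with tie and continuity
    correction is used. If every value in both samples is identical the
    conventional p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if exact is None:
        exact = x.size <= 10 and y.size <= 10 and not has_ties
    if exact and has_ties:
        warnings.warn("ties present: falling back to the normal approximation")
        exact = False
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


_VDA_BANDS = (
    # (low, high, label) on A rounded to 2 decimals; printed interpretation
    # ranges for the A statistic, which partition [0, 1] at that granularity.
    (0.00, 0.295, "large"),
    (0.295, 0.345, "medium"),
    (0.345, 0.445, "small"),
    (0.445, 0.555, "negligible"),
    (0.555, 0.635, "small"),
    (0.635, 0.705, "medium"),
    (0.705, 1.00, "large"),
)


def interpret_vda(a: float) -> str:
    """Interpretation band for Vargha–Delaney A: negligible 0.45–0.55;
    small 0.56–0.63 or 0.35–0.44; medium 0.64–0.70 or 0.30–0.34; large
    above 0.70 or below 0.30."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    for low, high, label in _VDA_BANDS:
        if low <= a < high:
            return label
    return "large"  # a == 1.0


def vda_effect_size(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Vargha–Delaney A: probability of superiority of ``x`` over ``y``
    with ties credited one half; 1 means complete stochastic dominance of
    the first group, 0.5 no difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    a = (np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size
    return float(a), interpret_vda(a)


def interpret_cohen_d(d: float) -> str:
    """Conventional |d| bands: <0.2 negligible, <0.5 small, <0.8 medium."""
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# Correlation


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    t approximation with df = n − 2. Zero variance → (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for z, via the
    first-order partial-correlation formula on the pairwise rank
    correlations; p from the t approximation with df = n − 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (n == y.size == z.size) or n < 4:
        raise ValueError("need aligned vectors with n >= 4")
    rxy, _ = spearman(x, y)
    rxz, _ = spearman(x, z)
    ryz, _ = spearman(y, z)
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0 or np.isnan(denom):
        return float("nan"), float("nan")
    rho = (rxy - rxz * ryz) / denom
    df = n - 3
    rho_c = min(max(rho, -0.9999999), 0.9999999)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Parametric comparisons


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p).
    Zero variance in both groups with equal means → t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohen_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled (n−1 weighted) standard deviation,
    signed mean(x) − mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r×c count table with
    df = (r−1)(c−1); no continuity correction. A zero row or column
    marginal makes the test undefined (ValueError)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: test undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic fit with the reporting battery.

    Coefficient tables are indexed by term name (``const`` first). Odds
    ratios and their Wald 95% CIs are exp-transformed coefficients;
    ``classification_rate`` is at the 0.5 probability threshold;
    diagnostics (Hosmer–Lemeshow, Box–Tidwell, VIF, Cook's distance) are
    attached lazily by the corresponding functions or by the pipeline.
    """

    params: pd.Series
    bse: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    odds_ratios: pd.DataFrame  # columns: or, ci_low, ci_high
    n_obs: int
    deviance: float
    null_deviance: float
    aic: float
    model_chi2: float
    model_df: int
    model_p: float
    r2_cox_snell: float
    r2_nagelkerke: float
    classification_rate: float
    baseline_rate: float
    fitted_probs: np.ndarray
    outcome: np.ndarray
    exog: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Coefficient table: b (SE), Wald z, p, OR (95% CI)."""
        return pd.DataFrame(
            {
                "b": self.params,
                "se": self.bse,
                "wald_z": self.wald_z,
                "p": self.p_values,
                "odds_ratio": self.odds_ratios["or"],
                "or_ci_low": self.odds_ratios["ci_low"],
                "or_ci_high": self.odds_ratios["ci_high"],
            }
        )


def _check_separation(params: np.ndarray, probs: np.ndarray) -> None:
    eps = 1e-8
    if np.all((probs < eps) | (probs > 1 - eps)) or np.abs(params).max() > 50:
        raise SeparationError(
            "perfect or quasi-complete separation detected: coefficients "
            "diverge and Wald statistics are meaningless; remove or combine "
            "the offending predictor(s)"
        )


def logistic_fit(design: pd.DataFrame, outcome: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood binary logistic regression of ``outcome`` on the
    predictors in ``design`` (an intercept is added).

    Reports Wald z per term, odds ratios with Wald 95% CIs, Cox & Snell
    R² = 1 − exp((D − D₀)/n), Nagelkerke R² (Cox & Snell rescaled by its
    maximum 1 − exp(−D₀/n)), AIC = D + 2k, the likelihood-ratio model
    chi-square, and the 0.5-threshold classification rate against the
    majority-class baseline. Perfect separation aborts with
    :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame(design).astype(float).reset_index(drop=True)
    if X.isna().any().any():
        raise ValueError("missing cells in the design matrix")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, tol=1e-8)
        except Exception as exc:  # PerfectSeparationError and kin
            raise SeparationError(str(exc)) from exc
    probs = np.asarray(res.predict(Xc))
    _check_separation(np.asarray(res.params), probs)

    n = len(y)
    deviance = float(-2 * res.llf)
    null_deviance = float(-2 * res.llnull)
    k = Xc.shape[1]
    cs = 1.0 - np.exp((deviance - null_deviance) / n)
    cs_max = 1.0 - np.exp(-null_deviance / n)
    nagelkerke = cs / cs_max if cs_max > 0 else float("nan")
    or_point = np.exp(res.params)
    ci_low = np.exp(res.params - 1.96 * res.bse)
    ci_high = np.exp(res.params + 1.96 * res.bse)
    pred = (probs >= 0.5).astype(float)
    classification = float((pred == y).mean())
    baseline = float(max(y.mean(), 1 - y.mean()))
    model_df = k - 1
    model_chi2 = null_deviance - deviance
    model_p = float(sps.chi2.sf(model_chi2, model_df)) if model_df > 0 else float("nan")
    return LogisticFit(
        params=pd.Series(res.params, index=Xc.columns),
        bse=pd.Series(res.bse, index=Xc.columns),
        wald_z=pd.Series(res.tvalues, index=Xc.columns),
        p_values=pd.Series(res.pvalues, index=Xc.columns),
        odds_ratios=pd.DataFrame(
            {"or": or_point, "ci_low": ci_low, "ci_high": ci_high}, index=Xc.columns
        ),
        n_obs=n,
        deviance=deviance,
        null_deviance=null_deviance,
        aic=deviance + 2 * k,
        model_chi2=float(model_chi2),
        model_df=model_df,
        model_p=model_p,
        r2_cox_snell=float(cs),
        r2_nagelkerke=float(nagelkerke),
        classification_rate=classification,
        baseline_rate=baseline,
        fitted_probs=probs,
        outcome=y,
        exog=Xc,
    )


def hosmer_lemeshow(
    probs: Sequence[float] | LogisticFit,
    outcome: Sequence[int] | None = None,
    n_groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit: deciles of risk by fitted
    probability (equal-frequency groups, ties kept together), chi-square
    over observed vs expected events and non-events, df = g − 2.

    Groups whose expected count is zero are merged into a neighbour with a
    warning. Accepts a :class:`LogisticFit` directly.
    """
    if isinstance(probs, LogisticFit):
        outcome = probs.outcome
        probs = probs.fitted_probs
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if p.size != y.size:
        raise ValueError("probs and outcome must align")
    if p.size < n_groups:
        raise ValueError("need at least one observation per group")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    # equal-frequency bin edges; identical fitted probabilities stay together
    edges = [int(round(i * p.size / n_groups)) for i in range(n_groups + 1)]
    for j in range(1, n_groups):
        while edges[j] < p.size and edges[j] > 0 and p[edges[j]] == p[edges[j] - 1]:
            edges[j] += 1
    groups = [
        (y[a:b], p[a:b]) for a, b in zip(edges, edges[1:]) if b > a
    ]
    # merge any group with a degenerate expected count into its neighbour
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for gy, gp in groups:
        e1, e0 = gp.sum(), (1 - gp).sum()
        if merged and (e1 == 0 or e0 == 0):
            warnings.warn("zero expected count: merging adjacent risk groups")
            py, pp = merged.pop()
            merged.append((np.concatenate([py, gy]), np.concatenate([pp, gp])))
        else:
            merged.append((gy, gp))
    g = len(merged)
    chi2 = 0.0
    for gy, gp in merged:
        o1, e1 = gy.sum(), gp.sum()
        o0, e0 = (1 - gy).sum(), (1 - gp).sum()
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = g - 2
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


def box_tidwell(
    design: pd.DataFrame,
    outcome: Sequence[int],
    continuous: Sequence[str],
    *,
    shift: bool = False,
) -> pd.Series:
    """Box–Tidwell linearity-of-the-logit check.

    Augments the logistic model with an x·ln(x) interaction per continuous
    predictor and returns the Wald p-value of each interaction term.
    Predictors must be strictly positive; with ``shift=True`` a +1 shift
    is applied first (for zero-containing counts), otherwise zeros raise.
    """
    X = pd.DataFrame(design).astype(float).copy()
    for col in continuous:
        v = X[col] + 1.0 if shift else X[col]
        if (v <= 0).any():
            raise ValueError(
                f"predictor {col!r} must be strictly positive for Box-Tidwell "
                "(pass shift=True for zero-containing counts)"
            )
        X[f"{col}_xlnx"] = v * np.log(v)
        if shift:
            X[col] = v
    fit = logistic_fit(X, outcome)
    return fit.p_values[[f"{c}_xlnx" for c in continuous]].rename(
        index={f"{c}_xlnx": c for c in continuous}
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor, VIF_j = 1/(1 − R²_j) from
    regressing predictor j on the others (with intercept). Perfect
    collinearity yields ``inf``."""
    X = pd.DataFrame(design).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    Xc = sm.add_constant(X, has_constant="add")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, col in enumerate(Xc.columns):
            if col == "const":
                continue
            out[col] = float(variance_inflation_factor(Xc.values, j))
    return pd.Series(out)


def cooks_distance(fit: LogisticFit) -> np.ndarray:
    """Per-observation Cook's distances from the one-step leave-one-out
    influence approximation on the IRLS working response (standardised
    Pearson residuals and hat values of the weighted design)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(fit.outcome, fit.exog, family=sm.families.Binomial()).fit()
        infl = glm.get_influence(observed=False)
        return np.asarray(infl.cooks_distance[0])


# ---------------------------------------------------------------------------
# Convenience


def compare_groups(
    x: Sequence[float], y: Sequence[float], *, method: str = "wilcoxon"
) -> GroupComparison:
    """Two-group comparison bundled with its effect size: ``wilcoxon``
    (rank-sum + Vargha–Delaney A) or ``welch`` (Welch t + Cohen's d)."""
    if method == "wilcoxon":
        w, p = wilcoxon_rank_sum(x, y)
        a, interp = vda_effect_size(x, y)
        return GroupComparison("W", w, p, "A", a, interp)
    if method == "welch":
        t, df, p = welch_t(x, y)
        d = cohen_d(x, y)
        return GroupComparison("t", t, p, "d", d, interpret_cohen_d(d), df=df)
    raise ValueError(f"unknown method {method!r}")
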