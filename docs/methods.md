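# Methods

This note documents the measures, the statistical battery, the synthetic
cohort generator and the numerical conventions used throughout `emovoc`,
together with the design choices that were genuinely open.

## Measures

**Tokenisation.** Lowercased alphabetic tokens with internal apostrophes
preserved (`[a-z]+(?:'[a-z]+)*` after case-folding and normalising curly
apostrophes); digits and punctuation are discarded. Contractions are kept
as single tokens (`i'd`) and never expanded — counts are reproducible only
if the token definition is fixed, so it is centralised in
`textscore.tokenize` and used by every stage.

**Stopwords.** A packaged ~180-word function-word list plus transcription
fillers (*hmm, ahm, ehm, um, …*). Spoken-interview transcripts contain
filler sounds that written-text stopword lists miss; the filler set and
the base list are both configurable because no two published stopword
collections agree exactly.

**Emotion lexicon.** An exact-match set of affective-state terms, each a
base form with optional syntactic variants (*angry → anger, angrily*) and
one of five categories (anger, anxiety, sadness, positive, other_affect).
Variant expansion is data-driven, not algorithmic stemming: stemming
over-matches (e.g. *moved → move*), while a curated variants column keeps
the judgement about semantic identity explicit. Matching is
case-insensitive and without lemmatisation. The packaged file is a
compact ~65-base-term lexicon (~150 terms with variants) spanning the
five categories — a working approximation of a full published affective
taxonomy, adequate for the synthetic corpora generated here; for real
data the lexicon file is an input and should be replaced by the analyst's
preferred taxonomy.

**Category dictionary.** A wildcard-capable pattern table in the open
`.dic` dialect (literal tokens or prefix patterns `hate*`, each crediting
one or more overlapping categories). The packaged dictionary covers the
packaged lexicon with affect/posemo/negemo plus the three specific
negative-emotion categories. Category percentages are computed over
stopword-filtered content tokens; categories overlap by design (anger ⊂
negemo ⊂ affect).

**EV and TTR.** EV = 100 · (unique emotion types) / (content words);
TTR = 100 · (distinct types) / (content words). Both use the content
count *with emotion words retained* in the denominator: for interviews
provoked entirely by emotional scenarios, emotion words can be a large
share of the response, and removing them would distort the denominator.
Both are reported on a 0–100 scale. When a participant has no content
words the ratios are *missing*, never zero.

**"feel" bigrams.** Within-response bigrams whose first token is *feel /
feels / feeling*, in three nested views: all; second token not a stopword;
second token also not in the emotion lexicon (the residual "feel —"
constructions that bag-of-words counting would miss). Bigrams never span
item boundaries.

**Questionnaires.** TAS-20: Likert-5 items, reverse-keyed set {4, 5, 10,
18, 19} (the published standard key; configurable), total = sum after
v → 6 − v reversal, alexithymic range at total ≥ 61. AQ-10: Likert-4
items collapsed to 0/1 (a point when the response falls on the keyed
side; agree-keyed set {1, 7, 8, 10}, configurable), screen positive at
≥ 6. A participant with any missing or out-of-range item has that
instrument marked missing — totals are never imputed. The automated APRQ
rating scores an item 1 iff the response contains at least one
emotion-lexicon token. This is an explicit approximation of the human 0/1
rating: human raters also score responses describing physical sensations
or the situation as alexithymic, context the lexicon rule cannot see, so
automated totals should be read as an upper bound on affect naming, not
as a clinical rating.

**Reported percentages** round half-to-even at the printed precision
(5/32 → 15.6, 18/32 → 56.2, 32/63 → 50.79).

## Statistical battery

Group comparisons of linguistic counts use the Wilcoxon rank-sum test:
linguistic count data are heavy-tailed (Zipf/Heaps behaviour), so
rank-based tests are the default. The reported statistic W is the
Mann–Whitney U of the first group, so the Vargha–Delaney effect size is
A = W/(n_x·n_y). The p-value is exact (full enumeration) when both groups
have n ≤ 10 without ties; otherwise the normal approximation with tie and
continuity correction is used. An opt-in `exact=True` exists for larger
samples. Ties in A are credited ½. Interpretation bands (negligible
0.45–0.55; small 0.56–0.63 or 0.35–0.44; medium 0.64–0.70 or 0.30–0.34;
large > 0.70 or < 0.30) are applied to A rounded to two decimals so the
published band edges partition [0, 1]. Two-sided p-values throughout; no
multiple-testing correction is applied by default (matching standard
exploratory practice for this design).

Congruence analyses use Welch's t (fractional Satterthwaite df) and
Cohen's d with pooled SD, first group minus second, at the level of the
individual item response pooled over participants (participant-level
aggregation is an option). Partial Spearman correlation uses the
first-order partial-correlation formula on the pairwise rank
correlations, with a t approximation on n − 3 df; whether a partial rank
correlation should be residualisation- or formula-based is a genuine
choice — the formula route is used because it is deterministic, matches
`pingouin.partial_corr(method="spearman")` (cross-checked in the tests),
and has a standard reference distribution.

Logistic regression is a maximum-likelihood fit (Newton/IRLS, tolerance
1e-8) of group membership. Reported per model: coefficients with SE, Wald
z, odds ratios with Wald 95% CIs, Cox & Snell R² = 1 − exp((D − D₀)/n),
Nagelkerke R² (Cox & Snell divided by its maximum 1 − exp(−D₀/n)),
AIC = D + 2k, the likelihood-ratio model χ², and the 0.5-threshold
classification rate against the majority-class baseline. Perfect or
quasi-complete separation (all fitted probabilities degenerate, or any
|coefficient| > 50) aborts the fit with a diagnostic error rather than
returning meaningless Wald statistics. Diagnostics: Hosmer–Lemeshow on
equal-frequency deciles of fitted risk (ties kept together; zero-expected
groups merged with a warning; df = g − 2), Box–Tidwell x·ln(x)
interactions (strictly positive predictors required; a documented +1
shift is available for zero-containing counts), VIF per predictor, and
Cook's distances from the one-step leave-one-out approximation on the
IRLS working response (verified against explicit leave-one-out refits in
the tests).

## Synthetic cohort generator

The generator emulates the statistical structure of a two-group
emotion-provocation interview corpus; it makes no attempt at natural
language — every downstream operation is bag-of-words or bigram based, so
token frequencies are all that matters, and the neutral vocabulary is
synthetic (`q`-prefixed pseudo-words that cannot collide with lexicon or
stopword entries).

Per participant: a latent expressiveness trait z ~ N(0, 1) modulates the
emotion-emission rate on the logit scale (spread `latent_sd`); the raw
interview length is log-normal (linguistic counts are right-skewed) and
split over the 17 items by a Dirichlet-weighted multinomial; each item's
tokens are a mixture of stopwords/fillers, Zipf-distributed neutral
words, and emotion words. Emotion words are drawn from the provocation's
congruent category sublexicon (with probability `incongruence_prob` a
token switches to a non-matching category; unclassified items elicit one
randomly chosen category per item), with per-participant Dirichlet
term-preference weights whose concentration (`emotion_diversity`) scales
with interview length — a Heaps-law property without which short
interviews would show inflated EV ratios. Two structural choices encode
what real corpora show and a naive token model misses:

- **Emotion window.** Per item, emotion tokens are emitted from at most
  the first `emotion_window` (default 6) content-token slots: emotion
  terms sit in the direct answer clause while verbosity adds neutral
  elaboration, so emotion counts grow sublinearly with response length.
  Without this, emotion-count variance inherits the full length CV and is
  roughly twice what interview data show.
- **Length-scaled diversity** (above), which keeps the EV ratio stable
  across interview lengths.

AQ-10 totals are generated as a group base minus a multiple of z plus
noise (`trait_noise_sd`), giving the negative expressiveness–autism-trait
association the analysis expects to recover; TAS-20 totals carry a group
shift but are, by default, independent of expressiveness (the
TAS–word-use association is left as a free parameter because its true
population value is contested). Both instruments are back-generated into
item-level responses consistent with the target totals, so the scorers
are exercised end to end. "feel" bigrams are injected at ~0.18 per item.

`default_paper_profile()` fixes the study conditions: 32 per group, one
NT TAS-20 non-completer (63 questionnaire completers), raw interview
lengths with mean ≈ 1066 (ASD-like) vs ≈ 606 (NT-like) words and heavy
right skew, ≈ 80% stopwords, emotion word counts ≈ 24 vs ≈ 29 with SDs
near 12, non-emotion counts ≈ 185 vs ≈ 105, group-equal TTR, and
rank-based effect sizes near A ≈ 0.36 (emotion count), 0.31 (EV), 0.67
(non-emotion count). These defaults were calibrated once against the
published summary statistics of a 32-per-group APRQ corpus and then
frozen. EV *levels* run ~3 percentage points above the published means —
a consequence of the compact lexicon and the synthetic token model — while
the group contrast and effect sizes match; conclusions that depend on EV
levels rather than contrasts should not be read off the generator.
`equal_groups_profile()` sets both groups to identical parameters for
null calibration.

What passing tests on synthetic cohorts do **not** show: robustness to
transcription noise, morphological variants absent from the lexicon,
negation ("not happy" counts as positive at the unigram level), or
context-dependent affect words — all properties of real transcripts that
a frequency-matched generator cannot emulate.

## Simulation sizes and numerical conventions

The nominal-alpha calibration uses 500 replicates (tests) / 300
(acceptance script) of the null profile at n = 16 per group with
shortened interviews (log-mean 5.0 ≈ 150 raw words), checked against the
binomial distribution of rejection counts at α = 0.05. The
effect-direction pattern check uses 120 (tests) / 60 (script) replicates
of the full default profile at n = 32 per group; "negligible TTR
difference" is operationalised as the TTR rank-sum test being
non-significant at α = 0.05, and the other directions are read from the
Vargha–Delaney A of the report (A below/above 0.5), the report's native
effect measure. Logistic parameter recovery is checked at n = 2000
(each coefficient within 2 SE) and n = 200.

Degenerate inputs: all-identical rank-sum samples return p = 1 by
convention; zero-variance correlations are NaN with a warning, not 0;
empty responses propagate as missing values; congruence cells with fewer
than two responses per group, or all-equal data, skip the test with a
warning; a zero row/column marginal makes the chi-square undefined.
Cohort generation, analysis and file output are fully deterministic given
the seed (JSONL output is byte-stable).

## Known limitations

- The APRQ auto-scorer is a lexicon rule, not a human rating; its totals
  are systematically liberal for responses that name an emotion word in a
  non-affective sense.
- The packaged lexicon is deliberately small; EV and emotion-count levels
  depend directly on lexicon coverage and are only comparable across
  analyses run with the same lexicon.
- Bag-of-words scoring cannot attribute emotions to their experiencer
  ("John irritates Mary") or handle negation; the bigram view is a
  screening device, not a fix.
- The two "compliment" items of the APRQ are not identified by number in
  the public literature, so positive provocations are left unclassified
  and untested in the congruence analysis.
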