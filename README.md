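# emovoc

Emotion-vocabulary analysis of structured emotion-provocation interviews
(APRQ-style transcripts), for researchers studying alexithymia and verbal
emotional expression in autistic and neurotypical adults.

Self-report alexithymia instruments such as the TAS-20 presuppose the very
metacognitive access they try to measure. An alternative is to provoke
emotion verbally — the Alexithymia Provoked Response Questionnaire puts 17
hypothetical scenarios to the participant ("when someone you love dies …
what do you feel?") — and to analyse the words of the answers directly.
`emovoc` implements that analysis end to end:

- **Lexicon scoring.** Responses are tokenised (lowercase alphabetic
  tokens, internal apostrophes kept, so "I'd run" → `i'd`, `run`) and
  scored against an exact-match affect lexicon (base terms plus syntactic
  variants, e.g. *angry/anger/angrily*) and against a wildcard-capable
  category dictionary in the classic `.dic` dialect (affect, posemo,
  negemo, anger, anxiety, sadness). A compact open lexicon and dictionary
  are packaged; both are configurable inputs.
- **Lexical measures.** For each participant, over the concatenated
  interview: raw and stopword-filtered word counts, distinct words,
  emotion and non-emotion tokens, **Emotion Vocabulary**
  (EV = 100 · unique emotion words / content words — an emotional
  *granularity* measure), the **type/token ratio**
  (TTR = 100 · distinct words / content words — a general verbal-diversity
  control), category percentages, and "feel …" bigrams with their
  stopword- and lexicon-filtered views.
- **Provocation congruence.** APRQ items are mapped to the emotion they
  are designed to provoke (anger: items 2, 3, 5, 6, 9, 10; fear/anxiety:
  4, 8, 14, 15; loss/sadness: 13); congruent and incongruent
  emotion-category percentages are compared between groups at the response
  level with Welch's *t* and Cohen's *d*.
- **Questionnaire scoring.** TAS-20 (reverse-keyed items v → 6 − v, total
  ≥ 61 = alexithymic range), AQ-10 (bimodal 0/1 scoring, ≥ 6 screens
  positive), an automated lexicon-based APRQ 0/1 rating, and Cronbach's α.
- **Statistics.** Wilcoxon rank-sum (exact by enumeration for small
  tie-free samples, otherwise the corrected normal approximation) with the
  **Vargha–Delaney A** probability-of-superiority effect size
  (A = [#(x>y) + ½·#(x=y)] / (n_x·n_y), with the standard interpretation
  bands), Spearman and partial Spearman correlation, chi-square, and
  binary logistic regression with Wald z, odds ratios, Cox & Snell and
  Nagelkerke R², AIC, classification rates, Hosmer–Lemeshow,
  Box–Tidwell, VIF and Cook's distances.
- **Synthetic cohorts.** A generator emits two-group cohorts (transcripts
  + questionnaire item responses + ground truth) with the statistical
  structure real interview corpora show — log-normal interview lengths,
  Zipf-distributed neutral words, provocation-congruent emotion tokens, a
  latent expressiveness trait linked to the AQ-10 — so the whole pipeline
  is testable without access to clinical recordings.

## Worked example

```python
import emovoc as ev

cohort = ev.generate_cohort(ev.default_paper_profile(), seed=2)
report = ev.run_full_analysis(cohort.transcripts, cohort.instruments)
print(report.group_tests.set_index("measure").round(3))
```

A typical synthetic cohort (32 per group) gives:

```
emotion_token_count      ASD   26.56 (  7.89)  NT   32.66 ( 11.20)  W= 303.5 p=0.005 A=0.296 (medium)
ev_percent               ASD    9.78 (  4.74)  NT   13.70 (  3.57)  W= 261.0 p=0.001 A=0.255 (large)
ttr_percent              ASD   64.77 (  6.75)  NT   67.47 (  5.63)  W= 376.0 p=0.069 A=0.367 (small)
non_emotion_word_count   ASD  227.62 (153.31)  NT  111.66 ( 66.80)  W= 792.5 p=0.000 A=0.774 (large)
tas model 74.6%  full 82.5%   AIC 73.33 / 52.32   Nagelkerke R2 0.66
HL chi2(8)=2.31 p=0.97   partial rho(AQ10, EV | TTR) = -0.34 (p = 0.007)
```

Read: the ASD-like group produces *fewer* emotion tokens and a *lower*
Emotion Vocabulary than the NT-like group (A well below 0.5), *more*
non-emotion words (A above 0.5), while general lexical diversity (TTR)
does not differ — the generator's default profile encodes exactly this
dissociation. Adding the two word-count predictors to a TAS-20-only
logistic model of group membership raises correct classification from
74.6% to 82.5% and drops the AIC by 21 points; the Hosmer–Lemeshow test
finds no calibration failure, and AQ-10 remains correlated with EV after
controlling for TTR.

The same pipeline runs from the shell:

```bash
emovoc simulate --seed 2 --out cohort/
emovoc score    --transcripts cohort/transcripts.jsonl --out features.csv
emovoc analyze  --transcripts cohort/transcripts.jsonl \
                --instruments cohort/instruments.csv --out report/
```

Real data enter through the same files: transcripts as JSONL
(`participant_id`, `group`, `responses` {item → text}) or long CSV, and a
one-row-per-participant instrument CSV (`tas_1..tas_20`, `aq_1..aq_10`,
optional `age`).

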