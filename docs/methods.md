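# Methods

This note documents the models, conventions, and numerical choices behind
`radalign`, and what the synthetic experiments do and do not demonstrate.

## The evidence-based recommendation model

The central object is a deterministic map from guideline **Topics** to sets of
appropriate imaging studies. Guidelines describe several clinical *variants*
per Topic, each with its own study set; a deterministic lookup needs exactly
one, so each Topic carries a curated **canonical variant** flag in the
knowledge-base snapshot. Canonical-variant choice is curation data — typically
the variant describing the acutely presenting patient the Topic name evokes
(for a suspected pulmonary embolism, the high-pretest-probability variant,
whose appropriate studies are CTA of the pulmonary arteries with IV contrast
and a V/Q lung scan). The library validates uniqueness of the flag; it never
infers it. Topics whose guidance warrants no imaging resolve to the sentinel
pseudo-study `"None"` (`"No Imaging"` accepted as an alias), which is a full
member of the study vocabulary, and exactly one vocabulary entry may carry the
sentinel flag.

A case is evaluated as follows: the completion backend is prompted for up to
*m* Topics; each parsed Topic is resolved through the knowledge base; the
predicted study set `K_pred` is the union of the resolved sets. When the
union mixes the sentinel with real studies, the sentinel is dropped
(configurable): a predicted topic that warrants imaging dominates one that
does not. The baseline comparison pipeline instead asks the backend for an
imaging study directly and matches it against the vocabulary.

### Free-text normalization

Model output is free text, so topic names are matched in three stages: exact
match after case/whitespace/punctuation folding; otherwise the best token-set
similarity candidate, accepted only at similarity ≥ 0.90 (ties broken
alphabetically); otherwise *unmatched*. The threshold is deliberately
conservative — an off-guideline topic string should be scored wrong, not
silently mapped to the nearest name — and is configurable. Unmatched items in
a multi-item answer are dropped; a response in which nothing matches is
recorded as **unparsed**, scores 0 on all accuracy metrics, and is tallied
separately (`unparsed_fraction`). Silently dropping such cases would inflate
accuracy. Study names are matched exactly (after folding), with sentinel
aliases accepted.

Answer extraction takes the text after the final `Answer:` marker
(case-insensitive), falling back to the last non-empty line; items are split
on newlines, semicolons, and numbered-list markers. Prompt templates are
plain text with `{{one_liner}}` / `{{context}}` / `{{m}}` placeholders and can
be replaced by file.

## Metrics

For a case with ground-truth study set `K` and prediction `K_pred`:

- **Imaging accuracy** = |K_pred ∩ K| / |K_pred|; an empty `K_pred`
  (unparsed) scores 0 by convention, since the definition's denominator
  assumes a prediction exists.
- **Topic accuracy** is the exact-match indicator; with *m* > 1 a case counts
  as correct iff the single true Topic appears among the predictions.
- **FPR (unnecessary imaging)**: cases where `K = {None}` yet the prediction
  orders imaging. An unparsed case orders nothing and is therefore not a
  false positive, even though "None ∉ K_pred" holds vacuously.
- **FNR (missed imaging)**: cases where imaging is warranted
  (`None ∉ K`) yet `K_pred = {None}`.
- Both rates are reported over all evaluated cases (default) and over the
  cases satisfying the respective ground-truth condition (`conditional`
  mode); verbose reports carry both, since both readings appear in practice.
- **F1** = 2·TP/(2·TP + FP + FN), with TP the number of cases where a
  clinically indicated (non-sentinel) study was ordered.
- **Dice–Sørensen** 2|A∩B|/(|A|+|B|) compares two decision makers' study
  sets per case; the pairwise report gives the per-case values, their mean,
  and a Student-t 95% CI over cases.

A structural property worth stating: whenever the true Topic is among the
predictions, `K ⊆ K_pred` up to the union rule and the per-case imaging
accuracy of an evidence pipeline with m = 1 is exactly 1 — hence mean imaging
accuracy ≥ topic accuracy on any evaluation set. The test suite asserts this
dominance on every synthetic run.

Statistical comparisons are two-sample homoscedastic (pooled-variance)
t-tests (one- or two-tailed, direction supplied by the caller), paired t, and
McNemar on paired binary outcomes — exact binomial on the discordant pairs
when there are fewer than 25, χ² with continuity correction otherwise.
Identical or constant-difference inputs return p = 1 rather than NaN.
Confidence intervals are Student-t with n − 1 df.

## The prospective-study regression

The guidance effect is estimated by a linear probability model

y_{s,q} = β₀ + β₁·guidance_{s,q} + θ_q + χ_s + ε_{s,q}

with explicit question dummies θ_q (the first question is the omitted
reference; ~50 questions keeps explicit dummies tractable) and participant
covariates χ_s (physician vs student, AI experience, AI sentiment). A linear
(not logistic) model is used because the estimand is a difference in
probabilities. Point estimates come from least squares; covariate columns
with no variation are dropped automatically, and a singular design raises an
error naming a collinear column.

Inference on β₁ uses two-way cluster-robust standard errors by participant
and by question, combined by inclusion–exclusion:
V = V_participant + V_question − V_intersection, each one-way sandwich
carrying the G/(G−1)·(N−1)/(N−K) small-sample correction, with t inference on
min(G_s, G_q) − 1 degrees of freedom. With one observation per
(participant, question) cell the intersection component is the
heteroskedasticity-robust sandwich with the same correction.

The inclusion–exclusion combination need not be positive semi-definite. With
a large fixed-effect block it is routinely indefinite in directions
orthogonal to the guidance coefficient, where the indefiniteness is
harmless; unconditional eigenvalue truncation in that situation perturbs the
well-behaved diagonal entry of interest and makes the test badly conservative
(null rejection rates of 0.005–0.03 at nominal 0.05 in our simulations). The
implementation therefore repairs the matrix by truncating negative
eigenvalues **only** when the variance entry actually used for inference is
non-positive, flagging the result when it does. A constant (perfectly fit)
outcome returns β₁ with zero variance and a degenerate-variance warning
rather than an error.

## The synthetic generators

The generators produce the study conditions the package is tested under; all
are pure functions of (spec, seed).

- **Knowledge bases** contain a requested number of topics and studies, at
  least one topic resolving to the sentinel, non-canonical decoy variants on
  roughly half the topics, and **sibling pairs**: topic pairs with identical
  canonical study sets. Siblings reproduce the clinically important
  phenomenon of closely related scenarios (major blunt trauma vs penetrating
  torso trauma) warranting the same studies, which decouples topic accuracy
  from imaging accuracy.
- **One-liners** follow clinical telegraphic style
  (`"<age> <sex> with <risk factors> p/w <duration> hx of symptoms
  concerning for <condition>"`) so the sentence splitter and prompt plumbing
  face realistic text; labels are drawn uniformly over topics. The embedded
  condition lets mock backends recover the true label from the rendered
  prompt alone, keeping the backend contract identical to a real API's.
- **Confusion backends** emit, for a case with true topic *t*, a topic drawn
  from a row-stochastic confusion row for *t* (or non-matching text with a
  configured unparsed rate), deterministically per (prompt, seed) via a
  hash-derived RNG stream — satisfying the temperature-0 determinism
  contract.
- **Prospective grids** default to the emulated study design: 30 participants
  (23 students, 7 physicians) × 50 questions, guidance on a random half of
  the questions per participant, base correctness β₀ = 0.158 and guidance
  effect β₁ = 0.08 on the probability scale, centred Gaussian question
  effects (sd 0.05) and small covariate effects. Success probabilities are
  clipped to [0, 1] (matching the linear model being fit, not a logit); the
  clip count is recorded and a warning issued when clipping occurs.

What passing tests show — and what they do not: the synthetic text has none
of the ambiguity, misspellings, or distributional quirks of real clinical
one-liners, the confusion model is an idealization of real model errors, and
the miniature knowledge bases have a handful of topics rather than hundreds.
The suite therefore validates the *mechanics* (lookup determinism, metric
identities, estimator calibration, parsing robustness), not the clinical
performance of any particular language model.

## Simulation sizes and numerical choices

- Retrieval rankers are verified against exhaustive score-and-sort oracles on
  corpora of ≤ 10 chunks; BM25 uses the non-negative idf
  ln(1 + (N − df + 0.5)/(df + 0.5)) with k1 = 1.5, b = 0.75 and
  lowercase/non-alphanumeric-split tokenization without stemming. Ranking
  ties break toward the lower chunk id.
- Corpus chunking greedily accumulates paragraph units (oversize paragraphs
  split at sentence boundaries), flushing before a chunk would exceed
  2048 characters; under-minimum tails are flagged rather than merged across
  sources, and re-concatenation of a source's chunks reproduces the source
  text exactly.
- The sibling-confusion experiment uses ~2000 cases at confusion probability
  0.5 and checks the binomial 3σ band around topic accuracy 0.5 with imaging
  accuracy exactly 1.
- Regression effect recovery averages β̂₁ over 12 grids at the study-design
  size (30 × 50). Null calibration runs 2000 replicates on a 40 × 40 grid:
  cluster-robust calibration is a many-clusters property, and with only 20
  clusters alongside ~20 absorbed fixed effects the well-known few-cluster
  distortion would dominate what the check is meant to verify.
- The McNemar calibration simulation uses 400 paired outcomes so the test
  operates in its χ² regime; the exact-binomial branch is intrinsically
  conservative at small discordant counts (discreteness of the binomial), and
  the unit suite bounds it one-sidedly instead.
- Percentages in dataset summaries are rounded to one decimal, half away from
  zero.

## Known limitations

- Fuzzy topic matching is token-set based; it will not bridge synonyms or
  abbreviations that share no tokens with the canonical name ("PE" will not
  match "Suspected Pulmonary Embolism"). Real deployments should extend the
  knowledge base with alias lists.
- The first-sentence splitter's abbreviation guard is a fixed list; unusual
  abbreviations ending in a period followed by a capitalized word will still
  split early.
- The regression assumes one observation per (participant, question) cell;
  repeated measurements require aggregation upstream.
- Embedding retrieval ships the contract and the ranking only; no embedding
  model is bundled.
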