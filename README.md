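# radalign

Evidence-based diagnostic imaging-order recommendation and its evaluation.

Ordering the right imaging study for an acutely presenting patient is hard:
clinicians work from terse "one-liner" case summaries with limited context,
and direct model recommendations frequently disagree with evidence-based
guidelines such as the ACR Appropriateness Criteria. `radalign` implements an
alternative pipeline: a language model is asked only to *classify* the
one-liner into a guideline **Topic** (a named clinical scenario), and the
appropriate imaging studies are then resolved **deterministically** from a
versioned Topic → study-set knowledge base — the model never picks the study
itself. The package provides everything needed to build, run, and statistically
evaluate such pipelines at desk scale, with a pluggable completion backend so
that deterministic mock models stand in for API calls.

## What is in the box

- **`radalign.kb`** — the guideline knowledge base: Topics with clinical
  variants, one canonical variant per Topic, a fixed imaging-study vocabulary
  with a no-imaging sentinel (`"None"`), JSON snapshot I/O, validation, and
  conservative fuzzy normalization of free-text topic names (token-set
  similarity ≥ 0.90).
- **`radalign.dataset`** — one-liner records with subset tags, ground-truth
  Topic labels and exclusion-reason annotations; first-sentence extraction
  with a clinical abbreviation guard; JSONL/CSV round-trip I/O; summaries
  (subset sizes, exclusion breakdown, topic coverage).
- **`radalign.retrieval`** — corpus segmentation into bounded character
  windows (1119–2048 by default) plus three retriever families for RAG/ICL
  context: Okapi BM25, cosine similarity over a pluggable embedder, and a
  uniform random baseline.
- **`radalign.prompting`** — prompt templates for baseline, chain-of-thought
  (four reasoning styles), in-context-learning and retrieval-augmented
  strategies; the completion-backend contract (deterministic at temperature 0
  for a fixed seed); robust parsing of free-text answers into canonical
  Topics or studies.
- **`radalign.pipelines`** — the baseline (direct study recommendation) and
  evidence-based (Topic classification + guideline lookup) pipelines and a
  multi-seed benchmark runner.
- **`radalign.metrics`** — imaging accuracy |K_pred ∩ K| / |K_pred|, topic
  accuracy, unnecessary-imaging (FPR) and missed-imaging (FNR) rates, F1 =
  2·TP/(2·TP + FP + FN), Dice–Sørensen set overlap, t-based confidence
  intervals, and two-sample/paired t and McNemar comparisons.
- **`radalign.study`** — the prospective-study regression: a linear
  probability model of a binary outcome on a guidance indicator with question
  fixed effects and participant covariates, inference via two-way
  (participant × question) cluster-robust standard errors.
- **`radalign.synthetic`** — generators for miniature knowledge bases (with
  sibling topics sharing study sets), labeled one-liners, confusion-driven
  mock backends, and participant × question response grids with a known
  guidance effect.

## Worked example

```python
import radalign as ra

spec = ra.SimulationSpec(n_topics=6, n_studies=8, n_sibling_pairs=1)
kb = ra.make_kb(spec, seed=1)
cases = ra.make_cases(kb, n_per_topic=1000, seed=7)

# a backend that confuses each sibling topic with its partner half the time
from radalign.synthetic import sibling_pairs
sib = sibling_pairs(spec)
confusion = ra.ConfusionModel.sibling_confusion(kb, sib, p=0.5)
backend = ra.make_confusion_backend(kb, confusion, seed=6)

sib_cases = [c for c in cases if c.label in sib]
evals = ra.run_benchmark(sib_cases, ra.RunConfig(seeds=[0]), backend, kb)
report = ra.metric_report(evals)
print(f"topic accuracy   {report.topic_accuracy:.3f}")
print(f"imaging accuracy {report.imaging_accuracy:.3f}")
```

```
topic accuracy   0.502
imaging accuracy 1.000
```

The backend misidentifies the Topic on roughly half of the cases, yet every
imaging recommendation is still fully guideline-appropriate, because the
confused Topics are *siblings* that warrant the same studies — the
"right study through the wrong reasoning" phenomenon that makes Topic
accuracy and imaging accuracy genuinely different quantities.

The same library drives a command line:

```sh
radalign simulate kb --out kb.json --seed 3
radalign simulate cases --out cases.jsonl --seed 3
radalign evaluate --dataset cases.jsonl --kb kb.json --out evals.jsonl
radalign metrics evals.jsonl
radalign simulate study --out study.csv --seed 3
radalign analyze-study study.csv
```

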