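# switchscope

Tools for studying **why patients switch contraceptives** using the two
kinds of evidence an electronic health record holds: structured medication
orders (what was prescribed, when) and free-text clinical notes (why the
plan changed). The package builds a treatment-switching cohort from order
tables, extracts *(stopped, started, reason)* triples from the associated
notes, scores those extractions against gold and silver labels, clusters
the extracted rationales into topics, and asks which topics are enriched
in which patient subgroups.

Because real clinical notes cannot be redistributed, the package ships a
synthetic-EHR generator that plants known switch dynamics, reason topics,
subgroup enrichments and realistic documentation noise — so the entire
pipeline is testable end-to-end offline, with the generator's bookkeeping
as ground truth.

## What it computes

**Cohort and switches.** Orders are selected by therapeutic class, mapped
to six modalities (oral, implant, IUD, injectable, transdermal,
intravaginal) through an editable regex table, then filtered in a fixed
attrition sequence: exclusion patterns (emergency/non-drug contraception),
missing start dates, six-month follow-up, missing or short (≤50-token)
notes, and per-encounter duplicates — each step recorded in an attrition
report. A **switch** is a difference between the modality *sets* of a
patient's consecutive encounters ordered by prescription start date, with
`stopped = previous \ current` and `started = current \ previous`.

**Extraction and evaluation.** A pluggable extractor contract maps one
note to *(stopped, started, reason)*; the shipped reference implementation
is a deterministic cue-phrase scanner (an LLM adapter can be slotted in
behind the same interface). Extractions are scored with micro-averaged
F1 over the six modalities (none excluded from the positive set), and
structured-data **silver labels** are compared with note-level gold labels
via Cohen's κ = (p_o − p_e)/(1 − p_e), with a restricted variant that
drops notes whose reference label is none. A learning-curve harness trains
bag-of-words/TF-IDF baselines on silver labels at decreasing training
fractions.

**Topics and enrichment.** Extracted reasons are embedded (deterministic
TF-IDF by default, plugin seam for transformer embedders), reduced with
UMAP (5 components, 3 neighbours, Euclidean), and clustered with HDBSCAN;
notes with no reason share the reserved topic 0. With q(n,k) the topic-k
weight of note n and y(n,j) the subgroup indicator, the enrichment score is

    θ(k,j) = N · Σₙ q(n,k)·y(n,j) / ( Σₙ q(n,k) · Σₙ y(n,j) )

reported as log θ, so independence of topic and subgroup gives 0, and
positive values mean the topic is over-represented in that subgroup.
Subgroups come from race/ethnicity categories or age bins (<21, 21–30,
31–40, 40+).

## Worked example

```python
from switchscope.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="demo", seed=3,
                simulate={"n_patients": 2000, "switch_probability": 0.25})
bundle = run_pipeline(cfg)
```

This simulates 2,000 patients (25% switchers, default documentation
noise), runs every stage, and writes the report bundle under `demo/`.
With this seed it detects **548 switch events**; the attrition report
shows 7,340 order rows entering and 3,523 surviving (e.g. 1,912 removed
as per-encounter duplicates, 650 for missing/short notes — exactly the
counts the generator planted). The evaluation report reads:

```
started  micro F1 0.996     stopped  micro F1 0.994
reason accuracy 1.000       hallucination rate 0.000
silver-vs-gold kappa: started 1.000, stopped 0.874
                      stopped (restricted to relevant notes) 1.000
```

The stopped-label κ is below the started-label κ because a fraction of
switch notes never mention the drug being discontinued — the structured
orders still record it, so silver and gold disagree; restricting to notes
with a relevant reference label removes exactly that disagreement. Age at
first prescription differs between switchers and non-switchers (25.7 vs
29.3 years, two-sided t = −8.2, p < 0.001), mirroring the planted age
model. Topic modelling finds 7 reason topics at this scale, and the
race-axis enrichment matrix (topics × 6 categories, log θ) is written to
`demo/enrichment_race.csv`.

Each stage is also a CLI subcommand:

```bash
switchscope simulate --seed 5 --out sim/
switchscope cohort --orders sim/orders.csv --notes sim/notes.jsonl --out coh/
switchscope extract --notes sim/notes.jsonl --out extractions.csv
switchscope run --seed 3 --out demo/
```

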