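# Methods

This note documents the models and procedures switchscope implements, the
parameter choices that matter, what the synthetic-EHR generator does and
does not emulate, and the numerical conventions used throughout.

## Cohort construction and switch detection

Orders enter the pipeline as rows of (patient id, encounter date, start
date, drug name, therapeutic class); dates are integer day offsets from a
synthetic epoch, and "6 months" is fixed at 183 days everywhere.

Filters run in a fixed order, and the attrition report has one row per
filter with a conservation invariant (remaining after step i equals
remaining after i−1 minus removed at i):

1. **Therapeutic class** — keep rows whose class contains "contracept"
   (case-insensitive).
2. **Pattern mapping** — drug names map through an ordered,
   case-insensitive regex table (`switchscope/data/modality_patterns.yaml`,
   user-replaceable). Exclusion patterns (emergency contraception,
   condoms/diaphragms, spermicides, pH modulators) are tried first; the
   six modality groups follow, route-specific patterns before the broad
   oral ones so combination products resolve by delivery route. Unmapped
   names are dropped with a logged warning rather than an error: a shipped
   table can never enumerate a live formulary, and a user can extend it.
3. **Missing start date.**
4. **Follow-up** — a patient is kept if any encounter (order or note)
   falls at least 183 days after their *last* contraceptive order. The
   anchor is switchable to *first* (`followup_anchor`), since either
   convention is defensible; *last* is the default because it is the
   stricter reading for patients with long prescription histories.
5. **Missing/short note** — an order needs a note at the same
   (patient, encounter date) with more than `note_token_threshold` = 50
   whitespace tokens. Whitespace tokenisation stands in for a subword
   tokenizer deliberately: it removes a model dependency without changing
   the filter's semantics, and the threshold is configurable. If an
   encounter has several qualifying notes the longest is linked
   (ties broken by note id for determinism).
6. **Duplicates** — one order per (patient, encounter date, modality),
   first occurrence kept under a stable sort.

Encounters are then grouped into per-patient timelines ordered by start
date (ties: encounter date, then modality name). Each timeline entry
carries a modality *set*; a switch event is emitted for every consecutive
pair with unequal sets, with stopped/started defined by set difference.
This representation makes multi-method encounters well-defined: adding a
method while keeping another yields an event with an empty stopped set
complement handled naturally by the set algebra, and stopped ∩ started = ∅
by construction.

The Table-1-style demographic comparison uses a two-sided t test (equal
variance) for age and chi-square tests of homogeneity for categorical
variables, computed without continuity correction so the statistic equals
the textbook Σ(O−E)²/E; percentages are reported among non-missing values.
A variable constant in both groups is marked not applicable.

## Extraction and its evaluation

The extractor contract is one function per note: text in, (stopped,
started, reason) out, with stopped/started drawn from the closed modality
set or none. The reference implementation is a cue-phrase scanner:

- stop cues: "stopped", "discontinu", "removal of", "came off";
- start cues: "started", "starting", "switching to", "begin", "placed";
- reason: the clause following "because of"/"because"/"due to"/"reports",
  up to the sentence boundary.

After each cue, the *nearest* drug/modality mention within a 60-character
window is normalised through the same pattern table the cohort uses (so
the two mapping paths cannot drift apart); if nothing follows the cue, the
window just before it is scanned ("Mirena placed today"). When several
cues of one kind resolve, the last mention wins by default (notes state
the final plan at the end); `take_last=False` flips this. Deidentification
placeholders normalise to none — an extractor cannot recover a redacted
brand name, and pretending otherwise would hide a real failure mode.

Silver labels are derived from the structured switch events alone; when a
set difference has more than one modality the alphabetically first name is
taken (documented tie-break, e.g. {Oral, Transdermal} → Oral).

Scoring: micro-averaged precision/recall/F1 pool true/false positives and
false negatives over the six modalities with none excluded from the
positive set — predicting none on a positive gold is a false negative,
predicting a modality on gold none a false positive, and a none/none pair
contributes nothing. Cohen's κ uses observed agreement against
marginal-product chance agreement and returns an explicit undefined marker
when p_e = 1; the restricted variant drops pairs whose reference (first
argument) label is none before scoring. Reason accuracy and hallucination
rate are fractions over annotated records only; on synthetic data an
automatic adjudicator stands in for the human reviewer (reason accurate
iff it equals the planted reason; hallucination iff a non-empty extracted
reason does not occur verbatim in the note).

The learning-curve harness draws k independent 70/10/20
train/validation/test splits per fraction, subsamples the training side,
fits a bag-of-words or TF-IDF pipeline (logistic regression or random
forest; any factory with fit/predict is accepted), and reports mean/SD
micro F1 on the held-out test side. A replicate whose subsample collapses
to one class is skipped with a warning. Repeated random resplits were
chosen over classical k-fold partitioning because the 70/10/20 geometry
and cross-validation cannot coexist exactly; seeds are logged.

## Topic modelling

Reasons are embedded with a deterministic TF-IDF representation by
default; `embed` accepts any callable returning fixed-dimension vectors,
which is the seam for transformer embedders. Embeddings are reduced by
UMAP to 5 components with 3 neighbours under Euclidean distance
(seeded, hence single-threaded and reproducible) and clustered by HDBSCAN
(`sklearn.cluster.HDBSCAN`) with `min_cluster_size` = 10 exposed in
config; the cluster count is whatever the density clusterer selects.
Degenerate inputs bypass the manifold step: if the number of distinct
vectors is at most n_neighbours + 1 (or the input dimension is already at
most the target), clustering runs on the raw vectors, and an all-identical
input is a single topic by definition.

Topic 0 is reserved for notes with no extracted reason and for HDBSCAN
noise points; it is excluded from enrichment by default. Soft weights
q(n,k) are inverse-squared-distance memberships to cluster centroids in
the reduced space, renormalised per note (rows sum to 1 within 1e-6);
noise notes carry weight 1 on topic 0. Per-topic key terms use class-based
TF-IDF: each topic's texts pool into one pseudo-document and term t in
topic c scores freq(t,c) · log(1 + n_topics / n_topics_containing_t). A
manual merge map regroups discovered topics; q columns are summed within
groups, so each note's total weight is conserved exactly, and terms are
recomputed on the merged classes when texts are supplied.

## Enrichment

θ(k,j) = N · Σₙ q(n,k) y(n,j) / (Σₙ q(n,k) · Σₙ y(n,j)), reported as the
natural log. The N factor makes the ratio dimensionless: the numerator and
the product of marginals then agree in scale, so independence of topic and
subgroup gives θ = 1 and log θ = 0, which is what a reader needs for the
sign of a heat-map cell to mean over- or under-representation. The
un-scaled raw ratio is available behind `scale_by_n=False`. Useful exact
properties: for a partition y, the subgroup-size-weighted mean of θ(k,·)
is 1 for every topic; θ is invariant to duplicating every note; raising a
topic's weight inside a subgroup (renormalising rows) never lowers that
cell. Cells with a zero marginal are undefined and surface as explicit
missing values, never as zeros.

Age bins assign a < 21 to "<21", 21 ≤ a ≤ 30 to "21–30", 31 ≤ a ≤ 40 to
"31–40", and a > 40 to "40+" — the boundary age 40 goes to "31–40" under a
closed-upper-bound convention, stated here because bin labels like these
are conventionally ambiguous at the boundary. Race/ethnicity categories
are used verbatim (White, Latinx, Black or African American, Asian, Other,
Multi-Race/Ethnicity); unknown categories are logged and binned as Other,
and notes without demographics drop out of that axis.

`recover_planted_enrichment` ranks cells by log θ above a threshold
(default 0.3) and can suppress cells whose expected joint support under
independence is below `min_expected_count` = 5 notes: the log of a small
count is sampling noise, not signal, and without the guard a near-empty
cell can outrank a genuine effect.

## The synthetic-EHR generator

The generator is the package's test bed, not a clinical simulator. Its
defaults encode the study conditions the pipeline targets: a 7.6%
per-patient switch probability, first-prescribed modality shares
(oral 64.0%, intravaginal 12.5%, IUD 7.6%, injectable 6.0%, implant 5.5%,
transdermal 4.3%), race/ethnicity shares (White 44.1%, Asian 20.0%,
Latinx 15.5%, Black or African American 9.2%, Other 8.1%,
Multi-Race/Ethnicity 3.2%), ~97% English language preference, and ages
drawn from N(25.9, 7.7²) for switchers and N(29.1, 8.4²) for
non-switchers, clipped to [15, 55]. Switchers receive one switch plus
additional ones with probability 0.25 each; inter-switch gaps are
exponential with a configurable mean (400 days at desk scale, where only
the ordering of encounters matters). The default cohort size of 2,000
patients keeps a full pipeline run under half a minute while leaving
~150 switch notes for the topic stages.

Notes are templated: filler sentences free of cue words, plus, for switch
encounters, "stopped <brand>", "starting <brand>" and "because of
<reason>" cue sentences. Reason phrases are sampled, not enumerated: each
topic has a fixed core wording (two bag-of-words-equivalent orderings) and
every sampled phrase interleaves it with 2–7 modifiers from a shared
30-word pool at random positions. This gives the reason corpus the
property real extracted rationales have — no two are written identically,
with a continuum of pairwise distances inside a topic — which is exactly
what a 3-neighbour manifold step needs; a corpus of verbatim-repeated
phrases collapses into point masses and fragments. Device-specific topics
(IUD malposition, implant removal, patch irritation, missed pills) only
attach to switches stopping the matching modality.

Noise is planted with exact bookkeeping: every noise record is constructed
so that precisely one filter removes it (duplicates copy orders of
patients who survive follow-up; missing-note and short-note orders are
back-dated between real encounters so they cannot extend a timeline past
its follow-up anchor), and the planted-truth summary records per-filter
counts that the attrition report must reproduce exactly. Default rates
approximate the attrition proportions of a real order table: duplicates
0.50, missing note 0.12, missing start date 0.10, lost to follow-up 0.15,
short note 0.05, emergency-contraceptive rows 0.05, non-contraceptive
distractor rows 0.10. Two noise channels target the note text itself:
person-like brand names (Camila, Heather) are redacted to a placeholder in
2% of eligible switch notes (the deidentification failure mode — gold
labels keep the true modality, so extraction recall drops), and 10% of
switch notes omit the stopped drug entirely (`undocumented_stop`), which
is the mechanism that makes structured-data silver labels disagree with
note-level gold for stopping far more than for starting, and makes the
restricted-κ variant recover.

What the generator does **not** emulate: clinical language variety beyond
the templates, comorbidities, within-modality product switches,
multi-note encounters (the cohort stage tolerates them by taking the
longest note, but the generator emits at most one note per encounter), and
free-text ambiguity that would genuinely challenge an LLM. Passing the
noise-free exactness checks therefore shows the pipeline's plumbing and
metrics are correct — not that the reference extractor would perform at
any particular level on real notes.

## Calibration and recovery suites (problem sizes)

- **Null calibration**: 1,000 notes, 5 topics, four subgroups at shares
  0.4/0.3/0.2/0.1, Dirichlet-perturbed q independent of y, 100 seeded
  replicates; every per-cell mean log θ must lie within ±0.05 of 0 (the
  residual is the ratio-estimator log bias, ≈ −Var/2, about 0.03 for the
  smallest subgroup at this n).
- **Planted-effect recovery**: one (topic, subgroup) cell at 3× prevalence
  in cohorts of 2,000 switch notes, five generic topics, four balanced
  race categories, one-hot q from the generator's truth; the planted cell
  must be the arg-max log θ in ≥95 of 100 seeded cohorts. Balanced
  subgroups at this size put every cell's expected support near 100 notes,
  so the planted log θ ≈ 0.51 sits ~5 null standard deviations above
  chance.
- **Cluster recovery**: 3 topics × 50 sampled reasons, 10 seeds; ≥95%
  pairwise co-membership (Rand index) against the planted partition on
  every seed, median discovered topic count 3. The analogous check on
  numeric data uses three 20-point Gaussian blobs with separation far
  exceeding spread and requires exactly 3 topics per seed.

## Known limitations

- The regex table resolves a mention to the single left-most match; a
  sentence naming two products in one breath resolves to the nearer one,
  which is a heuristic, not language understanding.
- κ between silver and gold is undefined (None) on degenerate label
  distributions; downstream code must expect the marker.
- UMAP with a fixed random state runs single-threaded; large corpora pay
  for reproducibility with wall-clock time.
- Enrichment scores are descriptive associations. No significance test is
  attached to log θ, and nothing here supports causal readings.
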