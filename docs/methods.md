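# Methods

## Problem and scope

`lupusnlp` implements a family of five algorithms that assign a
lupus-nephritis phenotype label to a patient from EHR data: a
structured-data rule, a regex+structured rule, and three L2-regularized
logistic-regression models over clinical-concept features extracted from
notes. The real cohorts such algorithms are built on are protected patient
data, so the package also ships a synthetic corpus generator that emulates
the statistical and linguistic structure the algorithms rely on. Everything
downstream — extraction, featurization, training, evaluation, explanation —
is exercised against that generator, whose planted-signal bookkeeping
doubles as a test oracle.

## Cohort model

A patient record carries free-text notes (pathology, progress, consult,
discharge), ICD-9/10 diagnosis codes, urine-protein laboratory results
(protein/creatinine ratio or 24-hour collection; red-blood-cell casts as a
boolean), a stored encounter count, and an optional chart-review gold
label. The cohort-depth filter excludes patients with fewer than four
encounters before any text processing. "Encounter" is an opaque stored
count: whether it equals a note, a visit, or a billing event is a property
of the source system, not of these algorithms, so the package does not try
to infer it from notes (the loader only enforces the invariant that the
count is at least the number of distinct note dates).

Dates are day-granularity ISO strings; no algorithm in the package uses
temporal logic beyond "earliest note wins" in deduplication.

## Text processing

The concept tagger is a dictionary matcher, not a full UMLS mapper: a
shipped phrase→CUI lexicon (~30 phrases over 16 CUIs, fully
user-overridable as TSV) is scanned case-insensitively per sentence with
longest-match-wins overlap resolution. Word-sense disambiguation, lexical
variants, section detection and temporality are out of scope; the
downstream models only consume per-patient presence/counts of a fixed
concept inventory, which dictionary matching serves adequately.

Preprocessing: duplicate notes (identical after lowercasing and whitespace
collapse) keep only the earliest-dated copy (ties: lowest note id).
Sentence splitting cuts at `.`, `!`, `?` and blank lines, protected by a
small abbreviation list and by decimal numbers ("ratio of 0.8" never
splits).

Negation is NegEx-style and forward-only: a mention is negated when a
trigger ("no", "denies", "without", "negative (for)", "no evidence of",
...) ends within `scope_window` word tokens (default 6) before the mention
start in the same sentence, unless the trigger occurrence is part of a
pseudo-trigger ("no increase ..."). Six tokens is the conventional NegEx
window and is exactly wide enough to catch the documented hard case

> Negative renal disorder: either persistent proteinuria (> 0.5 g/day or
> + + +) or cellular casts.

where "negative" sits five word-tokens before "proteinuria".

The regex channel searches five concepts — nephritis classes II–V and
quantified proteinuria — with patterns stored in an editable YAML file.
The defaults cover roman/arabic numerals, the "LN" abbreviation and the
"stage 2 LN" paraphrase. By default the channel is **negation-aware**
(patterns run per sentence and hits inside a trigger scope are dropped),
which deliberately fixes the known failure mode where a naive keyword
search asserts "proteinuria (> 0.5" inside the negated criterion sentence
above; `respect_negation=False` reproduces the naive behavior so the two
can be compared.

## Feature representations

* **binary** — one indicator column per CUI positively mentioned by at
  least 30 patients (minimum document frequency).
* **count** — total positive-mention counts, minimum document frequency 40.
* **mixed** — exactly 13 columns: indicators for 7 curated lupus-nephritis
  CUIs (C0024143, C0268757, C0268758, C4053955, C4053958, C4053959,
  C4054543), indicators for the 5 regex concepts, and the structured
  baseline rule's 0/1 output (column "RENAL").

Document frequency counts patients (the classification unit), with a
per-note variant behind `df_unit="note"`. Mixed-mode CUI and regex
features are binary rather than counts — the published coefficient tables
for this representation read as indicator-style features and the
structured feature is explicitly binary — and this interpretation is
switchable by building a count matrix instead. No feature scaling is
applied anywhere (mixed features are 0/1; counts stay raw), and the model
metadata records that.

## Model

The classifier minimizes the weighted negative log-likelihood plus an L2
penalty, intercept unpenalized:

    G(β0, β) = Σ_i w_i [log(1 + exp(z_i)) − y_i z_i] + ‖β‖² / (2C),
    z_i = β0 + x_i·β

with balanced class weights `w(c) = n_total / (2 n_c)`. The optimizer is
L-BFGS-B on the analytic gradient (`gtol` 1e-8, `ftol` 1e-15, max 5000
iterations), started from zero — deterministic, and the convergence record
(iterations, final gradient norm) is stored on the model. Any deterministic
convex optimizer would define the same model; the objective is the
contract, and tests verify agreement with scikit-learn's independent
solver to 1e-6 in objective value.

`C` is tuned over {1e-5, …, 1e5} (11 log-spaced values) by mean accuracy
over stratified K-fold cross-validation (default 5 folds, seeded shuffle)
**within the training split**; the validation scheme behind "best
accuracy" is genuinely open in the source description, and in-split CV is
the standard choice. Ties go to the smallest `C` (strongest
regularization). Prediction thresholds probability at 0.5 with a strict
`>`, so a 0.49 score is negative and exactly-0.5 is negative.

The train/test split is 75/25, stratified by gold label with a fixed seed
(test set takes the ceiling: 472 labeled patients split 354/118);
stratification is a reproducibility choice and can be disabled.

## Evaluation and explanation

Sensitivity, specificity, PPV, NPV and F (harmonic mean of PPV and
sensitivity) come from the integer confusion matrix; a ratio with a zero
denominator is reported as absent rather than 0 or NaN. AUC is the
normalized Mann–Whitney U statistic (ties half), which is exact and
threshold-free. When matching published two-decimal metrics the package
rounds half-up, the convention of the printed tables.

`reconstruct_confusion` inverts rounding: exhaustive search over
`TP ∈ [0, n_pos] × TN ∈ [0, n_neg]` returns every integer matrix whose
sensitivity/specificity round to the printed values. On the 75-patient
external-validation cohort (14 positive / 61 negative) both published
rows reconstruct uniquely, and the implied PPV/NPV/F reproduce the rest of
each printed row — including the baseline row's F of 0.52, which does not
follow from the rounded (PPV, sensitivity) pair (those give 0.53).

Attribution is exact for a linear model: under the feature-independence
convention the Shapley value is `φ_ij = β_j (x_ij − x̄_j)` against a
background mean `x̄` (here: the training split), and local accuracy
`Σ_j φ_ij + baseline = β0 + β·x_i` holds to machine precision. A sampling
explainer would estimate the same quantity with Monte-Carlo noise, so the
closed form is used. Global importance is the mean absolute Shapley value
per feature.

## Synthetic corpus generator

Defaults emulate the source cohort's printed facts: prevalence 0.377,
notes per patient ~ round(max(1, Normal(68.58, 59.37))) (the two printed
moments; clamping at 1 biases the realized mean up by ≈ +3.7 notes, which
the tests' tolerance bands account for). Case notes plant positive concept
sentences (probability 0.12 per note) drawn from a weighted template bank
covering every lexicon concept, class II–V phrases (paraphrased as
"stage n LN" with probability 0.15), and quantified proteinuria; a planted
mention is negated with probability 0.10. Controls receive negated
mentions (rate 0.06/note), the boilerplate criterion sentence verbatim
(0.05/note), and rare stray positives (0.002/note — proteinuria of other
cause). 8% of notes are exact duplicates of an earlier note of the same
patient. Note types and departments are assigned uniformly (no per-type
frequencies are published).

Structured signal: cases carry a lupus-nephritis ICD code with probability
0.30 and controls with probability 0.30 (= 1 − specificity 0.70);
urine-protein labs are present with probability 0.5 (half of case labs
qualify, i.e. exceed ratio 0.5; 5% of control labs do); red-blood-cell
casts are rare (1% of cases). These rates are not printed anywhere; they
were fixed once to land near the source cohort's structured-data facts —
206/472 patients LN-coded, 230/472 with urine-protein results, and a
structured-only rule in the sensitivity ≈ 0.45 / specificity ≈ 0.7 regime —
and are recorded here rather than tuned.

What the generator does **not** emulate: realistic clinical prose,
inter-concept correlation beyond the case/control labels, temporal disease
course, misspellings, and note-type-specific language. Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
qualitative algorithm ordering (mixed > regex+structured > baseline
held-out F) emerges from the planted missing-lab/miscoding structure; they
do not certify performance numbers on real clinical text.

## Numerical and degenerate-input choices

* Probability exactly at threshold → negative (strict `>`).
* All-zero feature column → coefficient exactly 0 at the optimum (and the
  zero-initialized optimizer preserves that exactly).
* Corpus smaller than the document-frequency floor → empty feature matrix
  with a logged warning, not an error.
* Grid-search folds reduce (with a warning) when the minority class is
  smaller than the fold count; below 2 members it is an error.
* Labs on a different protein scale than configured are skipped with a
  logged warning, never silently compared.
* Deduplication ties (same date) break to the lowest note id; grid-search
  ties to the smallest `C`; coefficient-ranking ties to feature name.

## Pipeline and reproducibility

`run_all` chains simulate → extract → featurize → train → evaluate →
explain into one output directory with a manifest of SHA-256 content
hashes; identical config and seed give identical manifests. One global
seed fans out to stage seeds by fixed offsets (simulate +0, split +1,
train +2) so stages can be re-run alone. Stage failures abort with the
stage name and leave a `FAILED` marker beside any partial outputs.

The default experiment sizes (1000 simulated patients; 40–300 patients in
unit-test corpora) were chosen so the full suite and the acceptance script
each complete in well under a minute on one CPU while keeping binomial
noise small against the tested margins.

## Known limitations

* The dictionary tagger has no word-sense disambiguation; an ambiguous
  surface form ("kidney" in a medication instruction) counts as a mention.
* Negation is forward-only; post-position negation ("lupus nephritis was
  ruled out") is not caught — consistent with the trigger inventory, and
  extendable through `negation.yaml`.
* The shipped ICD code sets are reconstructed, not the source site lists;
  only set-membership logic is tested.
* Published AUC values depend on the protected test cohort and are not
  desk-reproducible; the package reports AUC on synthetic data only.
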