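# lupusnlp

Rule-based and NLP phenotyping algorithms for **lupus nephritis** in
electronic health records, with a synthetic EHR corpus generator for
end-to-end testing.

Lupus nephritis — kidney inflammation in systemic lupus erythematosus,
defined by the SLICC renal criterion (proteinuria ≥ 500 mg/24 h,
equivalently protein/creatinine ratio > 0.5, or red-blood-cell casts) — is
documented partly in structured EHR fields (ICD-9/10 codes, urine-protein
labs) and partly in free text (biopsy reports grading nephritis classes
II–V, progress notes). The package implements five phenotyping algorithms
of increasing sophistication and the tooling to evaluate and explain them:

1. **baseline** — structured rule: LN diagnosis code or proteinuria > 0.5;
2. **regex + structured** — baseline OR any hit of five nephritis text
   concepts (classes II–V, quantified proteinuria) found by negation-aware
   regular expressions;
3. **binary** / 4. **count** — L2-regularized logistic regression over all
   clinical-concept (CUI) mentions extracted from notes by a dictionary
   tagger with NegEx-style negation scoping (indicators resp. counts,
   minimum document frequency 30 resp. 40);
5. **mixed** — the same classifier over exactly 13 features: 7 curated LN
   CUIs + 5 regex concepts + the baseline rule's output.

The model is weighted logistic regression with an L2 penalty (intercept
unpenalized), balanced class weights `n/(2·n_c)`, `C` tuned over
1e-5…1e5 by stratified cross-validated accuracy, and a strict 0.5
probability threshold. Evaluation reports sensitivity, specificity, PPV,
NPV, F = 2·PPV·sens/(PPV+sens) and rank-based AUC; explanation uses exact
linear Shapley values `φ_j = β_j (x_j − x̄_j)`.

Real lupus cohorts are protected data, so the package ships a generator
that emulates their printed structure (prevalence 0.377, notes/patient
≈ 68.6 ± 59.4, configurable ICD sensitivity/specificity, lab missingness,
negated and paraphrased mentions, duplicated notes) with exact
planted-signal bookkeeping. See `docs/methods.md` for the full model and
generator description.

Intended users: clinical-informatics researchers prototyping EHR
phenotyping pipelines and anyone needing a self-contained, testable
reference implementation of concept-extraction-plus-regularized-regression
phenotyping.

## Worked example

```bash
lupusnlp run-all --out demo --seed 1 --n-patients 1000
```

simulates a 1000-patient labeled cohort, extracts concepts, builds the
three feature matrices, trains the three learned models on a stratified
75/25 split, and evaluates all five algorithms on the shared held-out
quarter. `demo/evaluation.csv`:

```
dataset,algorithm,sensitivity,specificity,ppv,npv,f_measure,auc
synthetic-test,baseline,0.453488,0.694444,0.469880,0.680272,0.461538,
synthetic-test,regex-structured,0.895349,0.652778,0.606299,0.912621,0.723005,
synthetic-test,binary,0.918605,1.000000,1.000000,0.953642,0.957576,0.956718
synthetic-test,count,0.918605,1.000000,1.000000,0.953642,0.957576,0.956718
synthetic-test,mixed,0.860465,1.000000,1.000000,0.923077,0.925000,0.952923
```

The structured-only baseline is crippled by missing labs (low sensitivity)
and miscoding (low PPV); adding negation-aware text concepts lifts F from
0.46 to 0.72; the learned models push it above 0.92 by discounting the
noisy structured channel. Top mixed-model coefficients
(`lupusnlp explain --model demo/models/mixed.json --k 5`):

```
C0024143        Lupus nephritis 10.0114
nephritis_class_II              8.4205
C4054543        Membranous lupus nephritis      7.3910
nephritis_class_III             6.8665
C0268757        Lupus glomerulonephritis syndrome, WHO class IV 6.6730
```

i.e. the lupus-nephritis concept itself carries the largest positive
weight, with histologic class mentions behind it — and the same ranking
appears in `demo/explain/mixed_shap.csv` as mean absolute Shapley values.

Auditing a published-style rounded row
(`lupusnlp reconstruct-cm --n-pos 14 --n-neg 61 --sensitivity 0.93 --specificity 0.98`):

```
TP=13 FP=1 TN=60 FN=1 PPV=0.9286 NPV=0.9836 F=0.9286
```

shows the unique integer confusion matrix consistent with those metrics on
a 75-patient cohort.

## Layout

```
src/lupusnlp/
  corpus.py     patient/corpus types, JSONL+CSV readers/writers, encounter filter
  synth.py      synthetic corpus generator with planted-signal bookkeeping
  concepts.py   dedup, sentence splitting, lexicon tagger, negation, regex channel
  rules.py      baseline and regex+structured rule classifiers
  features.py   binary / count / mixed feature matrices
  learn.py      penalized logistic regression, balanced weights, C grid search
  evaluate.py   split, metrics, AUC, confusion-matrix reconstruction, linear SHAP
  pipeline.py   run-all orchestration with hashed artifact manifest
  cli.py        `lupusnlp` command-line interface
  data/         editable defaults: lexicon.tsv, regex_concepts.yaml,
                negation.yaml, structured_rule.yaml
```
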