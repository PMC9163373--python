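# Methods

`famhist` extracts family history of psychiatric disorder from the free-text
paragraph of psychiatric admission notes and quantifies its association with
the mood-disorder diagnosis at admission. This note documents the models,
the synthetic cohort the package is validated on, and the numerical and
design choices a maintainer would want to know.

## The labeling problem

Each admission note is a single paragraph mixing chief complaint, present
illness, past history, family history, personal history and physical exam.
The target is a **quintet label**: five binary indicators over the ICD-10
categories named in the family history — F20 (schizophrenia), F32
(depressive episode), F31 (bipolar disorder), F28 (other non-organic mental
disorders), F29 (unspecified non-organic psychosis), in that fixed order. A
note is positive for a category iff some relative is described with it. A
patient hospitalized several times receives the bitwise OR of their notes'
quintets, so `merge_labels` is exactly the componentwise maximum
(commutative, associative, idempotent — tested exhaustively over all
2^5 × 2^5 quintet pairs).

## Rule-based annotator

Extraction is event-based, not named-entity recognition: an event is one
(kinship term, disease term) co-occurrence inside the family-history
context.

1. **Segmentation** — dictionary longest-match over the lexicon terms plus
   single characters; the concatenation of token surfaces reconstructs the
   input exactly, so offsets are reliable. Greedy longest match also
   prevents nested false hits (外祖父 is never re-read as 祖父;
   "grandmother" never yields an inner "mother"). An external segmenter can
   be registered under its own tokenizer id.
2. **Section location** — the span from the first section cue (家族史 in the
   default lexicon) to the next sentence terminator. Matching defaults to
   this span, falling back to the full text when no cue exists; a `full`
   scope is available.
3. **Events** — each disease term attaches to the nearest preceding kinship
   term in the same sentence (unknown relation if none). Negation scope is
   the comma/period-delimited clause containing a negation cue (否认 etc.);
   disease mentions inside a negated clause are discarded. These two scope
   rules are the simplest models consistent with how admission notes are
   written; the annotator's exactness on generator output (precision =
   recall = 1.0 on noise-free corpora, and in practice also with negation
   and distractors enabled) is a consequence of annotator and generator
   sharing the lexicon, and says nothing about recall on real clinical
   prose with unlisted surface forms.

Kinship degrees follow the standard consanguinity convention (first:
parents/children/full siblings; second: grandparents/aunts/uncles/
nieces/nephews; third: first cousins/great-grandparents), isolated in the
lexicon JSON so a site-specific definition can be dropped in. For the
association analysis all degrees collapse to one any-degree group, because
second/third-degree mentions are rare.

## Neural classifier

The classifier is the composition *encoder × head*:

- **small_contextual** (default): character embeddings + learned positional
  embeddings through a 2-layer pre-norm transformer (2 heads, feed-forward
  expansion 2×). It is randomly initialized and trained end to end — a
  desk-scale stand-in with the same interface as a 12-layer pretrained
  encoder.
- **pretrained_contextual**: the same architecture initialized from an
  external `.npz` weight archive (`encoder_weights`), for sites that have
  distilled or converted pretrained weights.
- **static_vectors**: a plain trainable embedding table with no context
  mixing — the word-vector baseline.
- **cnn head**: convolutions of widths {2, 3, 4} (128 filters each by
  default), ReLU, stride one, per-filter max pooling over positions,
  concatenation in ascending width order, then one fully connected layer to
  five logits.
- **fc head**: masked mean pooling and a single fully connected layer — the
  simplest baseline head.

(static_vectors, cnn) and (pretrained/small_contextual, fc) instantiate the
two standard comparators of the contextual-encoder + CNN model.

Sigmoid outputs give per-category probabilities; the decision threshold is
0.5 (configurable). The loss is mean per-label binary cross-entropy — the
standard choice for independent multi-label indicators. Training uses Adam;
after every epoch the validation micro-F1 is recorded and the parameters of
the best validation epoch are returned, which is what makes the 16%
validation split meaningful. The corpus is split 64/16/20
(train/validation/test) with largest-remainder rounding; splitting is
note-level by default to mirror the evaluation protocol, with
`group_by_patient=True` available to prevent a patient's notes from
straddling splits (recommended when estimating generalization to new
patients).

The whole network runs on a small in-package reverse-mode autodiff engine
over numpy (float32 compute; float64 switchable, used by the
finite-difference gradient checks in the test suite). Max pooling routes
gradients to the first maximum on ties; zero-padded positions contribute
zero vectors, so with zero biases padding can only add non-negative
pooled candidates (a tested invariant).

Grid search evaluates each configuration over R = 5 seeded repetitions on
the test split and ranks by mean test micro-F1 with stable ties. The
default grid is learning rate {1e-4, 1e-5} × batch size {16, 32} with 100
epochs, appropriate when fine-tuning a pretrained encoder; training the
small encoder from scratch converges far faster, and the scaled-down
experiments below use lr 1e-3 with 8 epochs.

A **hybrid post-filter** combines thresholded model probabilities with rule
events per note: `rule_and` (positive only where both agree — a precision
filter), `rule_or` (either fires — a recall filter), `model_only`
(identity).

## Evaluation protocol

Per-label confusion counts feed micro averaging (pool counts, then compute)
and macro averaging (compute per label, then unweighted mean); the two
diverge under label imbalance, which is why both are reported. Zero
denominators yield 0 (logged). **Accuracy defaults to per-decision**
(correct (note, label) cells over n × 5): under rare positives this is the
only convention consistent with accuracy near 0.97 coexisting with micro
precision near 0.57; subset accuracy (exact quintet) is also computed.
ROC points are swept over all score thresholds and AUC is the trapezoid
integral, which equals the pairwise concordance probability (tested to
1e-9 against a brute-force count and scikit-learn). Repeated runs report
sample mean ± sd (n−1); configurations are compared with a Welch t-test on
run-level metric values (both samples constant and equal → p = 1 by
convention).

## Synthetic cohort generator

The generator is the package's test bed: it produces corpora whose
statistical structure matches a reference cohort of 12,006 admission notes
(2,123 F31 / 5,353 F32 / 4,530 F33), with known ground truth at both note
and patient level.

- **Family-history rates** are patient-level Bernoulli probabilities per
  diagnosis group, defaulting to the reference cohort's event counts
  divided by group size (e.g. F31-group schizophrenia 145/2123). Because
  diagnosis → family-history rates are explicit, the true odds ratios of
  the association stage are known by construction.
- **Admissions per patient**: 1 + Poisson(0.3). Multiple hospitalizations
  demonstrably occur but no distribution is published; the rate is exposed
  in config. Each patient-positive category is voiced in each of the
  patient's notes with probability 0.7, resampled to hit at least one note,
  so the patient OR-invariant holds exactly.
- **Kinship mix** first/second/third = 1593/342/63 (normalized), the
  reference mention counts.
- **Note length**: integer lengths from a truncated normal on [60, 948]
  whose *truncated* mean and sd equal the configured 204.3 and 65.66. The
  parent normal is recalibrated by solving a two-equation moment system
  (scipy `fsolve` over `truncnorm.stats`), because naively truncating
  N(204.3, 65.66²) shifts the realized mean to ≈ 206.7 and shrinks the sd
  to ≈ 63.0 — both outside three standard errors at n = 12,006. Rendering
  meets the sampled length exactly by trimming trailing filler, never the
  family-history sentence; only when mandatory content alone exceeds the
  target (very short target with many events) is the length bumped up,
  which is rare enough to leave the moments intact.
- **Negation rate 0.8**: most real notes with no family history state the
  absence explicitly (否认…家族史), and some denial templates embed a
  concrete disease term so negation handling is actually exercised.
  **Distractor rate 0.3**: disease terms planted in present/past-history
  filler outside the family-history section, the adversarial case for
  section scoping. Both default rates are the package's own choice of a
  realistic regime; "clean" test corpora set both to 0.
- **Demographics** (age bands, sex, marital status, profession with
  retirees at 26.2% of 19 classes) follow the reference marginals per
  diagnosis group and are held fixed across a patient's admissions.

What the generator does **not** emulate: real clinical prose variability
(it realizes a finite template set), comorbidity structure, surface forms
outside the lexicon, typos, or section-order variation. Perfect rule-based
scores on generator output therefore validate the *mechanics* (scoping,
negation, attachment, merging), not real-world recall; the neural
classifier's scores likewise reflect a template world and should be read
as an upper bound.

## Association analysis

On the merged patient table: a Pearson chi-squared contingency test
(no continuity correction, statistic Σ(O−E)²/E, df (r−1)(c−1)) of family
history versus diagnosis group, and a multivariable binary logistic
regression with outcome MDD = 1 (F32/F33) vs BD = 0 (F31). The five
family-history indicators are always retained — non-significant ones are
reported, not dropped — while age (continuous), gender, marital status and
profession (categorical, most-frequent reference level) enter by
bidirectional stepwise selection on AIC (BIC selectable). The maximum
likelihood fit is a binomial GLM via IRLS; Wald 95% intervals are
exp(coef ± 1.96·SE), and reference levels are rendered as "1.00 (ref.)".
A term with |coef| > 15 is flagged as quasi-complete separation; if a
forced exposure is affected the whole result is marked non-convergent and
`report_ors` refuses. The diagnosis group of a patient whose admissions
disagree comes from the earliest admission (a strict mode errors instead).

## Problem sizes used in the checks

The bundled checks run at desk scale by design: the generator calibration
uses one 12,006-note corpus; metric identities use 1,000 random small
instances; logistic coverage uses 200 simulated cohorts of n = 2,000
(observed coverage within [92%, 98%] at nominal 95%); the scaled-down
classifier trains the 2-layer/dim-32 encoder with widths {2, 3} × 32
filters for 8 epochs on ≈ 2,000 clean notes (test micro-F1 ≈ 0.97 against
the ≥ 0.90 bar); sign recovery of configured protective odds ratios runs
the full synth → annotate → merge → regression chain over 50 seeds of 600
patients with elevated family-history rates (so that even the smallest
group retains enough exposed patients for a stable sign).

## Known limitations

- The lexicon is deliberately small; real deployments must extend it
  (surface variants, abbreviations, hedges) and re-validate negation scope.
- Kinship attachment is "nearest preceding in sentence"; it will mis-attach
  in sentences listing diseases before relatives.
- The from-scratch small encoder cannot stand in for a pretrained model's
  transfer behaviour; `pretrained_contextual` exists for that, given
  weights.
- Wald intervals undercover for very rare exposures; profile-likelihood
  intervals are not implemented.
- The stepwise procedure inherits the usual caveats of data-driven covariate
  selection (post-selection inference is not adjusted).
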