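# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests show.

## Problem setting

Given one admission's freestyle EHR note, the system predicts a TCM
disease (ranked top-k list) and the corresponding syndrome. Syndrome
differentiation is hierarchical here: a separate syndrome model exists
per disease, and the disease prediction selects which one is consulted.
The disease↔syndrome relation is many-to-many — a syndrome (for example
"phlegm-damp") can occur under several diseases, and one disease admits
several syndromes — which is why per-disease models over small syndrome
label sets are used instead of one flat classifier over all syndromes.

## Named-entity recognition

**Model.** Tokens (whitespace-delimited; the tokenizer is pluggable) are
embedded, encoded by a bidirectional recurrent network (tanh cells,
default 24-dimensional embeddings and hidden states), and projected to
per-tag emission scores. A linear-chain CRF with learned transition
scores over the BIO tag set (plus virtual START/STOP states; transitions
into START and out of STOP are −∞) scores whole tag sequences:

    score(y) = Σ_t e[t, y_t] + A[START, y_1] + Σ_t A[y_t, y_{t+1}] + A[y_T, STOP]

Training minimizes the exact negative log-likelihood; gradients are
computed analytically (forward–backward marginals for the CRF,
backpropagation through time for the encoder) and applied with Adam,
one sequence per step. Both inference routines are exact: the partition
function by the forward recursion in log space, decoding by Viterbi with
ties broken toward the lowest tag index so decoding is deterministic.
Finite-difference tests verify every gradient; enumeration tests verify
both recursions against brute force on all K^T paths of small instances.

The encoder is implemented directly on numpy arrays. It is deliberately
compact: the corpora here are short token sequences over a closed
lexicon, and the exact-inference CRF, not encoder capacity, determines
span quality at this scale. Character-level features (mean of character
embeddings added to the token embedding) are available behind a config
flag, default off. Early stopping monitors validation span F1 (exact
match on start/end/type) with patience 2 over a default 5 epochs, and
the best validation weights are restored.

**Structuring.** Decoded BIO runs become spans; a dangling I-tag is
repaired to B. Entities are grouped by section; each duration attaches
to the nearest preceding symptom in the same section (the relation the
annotation examples exhibit), and unpaired durations are logged rather
than guessed.

## Feature extraction

Surfaces are standardized by a synonym dictionary (unknown surfaces pass
through verbatim, logged). Mentions of the same canonical term in
different sections merge into one group (split-and-join). Each
duration-qualified symptom expands into the bare term plus a compound
`symptom|duration` term, so "coughing 3days coughing-phlegm 2days"
yields four features.

**Recency weighting.** The weight grid over N time units starts at
weight(0) = 0 and rises by a constant increment 1/N to weight(N) = 1;
reading it by recency, an occurrence n units in the past weighs
weight(N − n) = (N − n)/N — 1 for today, 0 at the horizon. The unit is
the day, with month = 30 and year = 365 days when parsing durations;
distances beyond N clip to weight 0, and undated occurrences weigh 1
(treated as current observations). Defaults: N = 365. A group's value is
the sum of its occurrence weights; values above a threshold τ (default
0: keep everything observed) populate the vector. The feature index is
frozen on the training split; out-of-vocabulary terms at prediction time
are dropped with a log entry.

The weighted vectors feed the syndrome ensembles; the disease classifier
instead consumes the entity token sequence (canonical terms plus
compound terms, in note order), since its convolution operates on token
adjacency rather than on a bag of weights.

## Disease classifier

A text-convolution network: the L-token input (truncated/zero-padded;
pad row of the embedding table held at zero) is embedded to an L×d
matrix; kernel banks of width d at heights L−1, L−2 and L−3 slide along
the token axis (valid convolution, stride 1), leaving feature surfaces
of 2, 3 and 4 rows; ReLU, max-pooling to one scalar per kernel,
concatenation, a fully connected layer and a softmax over the diseases.
That tall-kernel geometry is unusual but unambiguous and is implemented
as stated; the classic small heights (2, 3, 4) remain available as a
preset. Reference sizes are d = 100 and 256 kernels per height;
synthetic-corpus runs default to d = 32 and 32 kernels with L = 16,
which reaches ceiling on the generator's output at a fraction of the
cost. Training is cross-entropy with Adam and early stopping on
validation top-1 accuracy; an optional learning-rate grid (searched in
descending order) stands in for a larger hyperparameter search. All
gradients are analytic and finite-difference-checked. Ranked output
breaks probability ties by class index, so top-k lists are deterministic
and prefix-consistent.

## Syndrome ensembles

Per disease, four base learners are fitted on the same class-balanced
feature vectors: a back-propagation MLP (one hidden layer of 64), a
support-vector classifier (linear kernel), a random forest (100 trees)
and gradient-boosted trees (50 rounds, depth 4) — scikit-learn and
xgboost fits behind a uniform facade. Confidence is the learner's
predicted-class probability; for the margin-based SVC the one-vs-rest
decision values are min-max scaled per row and normalized to sum 1
(raw per-row min-max alone would pin the top class at 1.0 and disable
the tie-break). Hyperparameters with a non-trivial grid are selected by
k-fold accuracy (default 3) on a bootstrap resample of the training
pool.

Prediction is majority rule over the four votes. With four voters, 2–2
and 1–1–1–1 patterns occur, so the tie-break chain is fixed: vote count,
then mean confidence of the tied label's voters, then lexicographic
label order. The full ranking orders all voted labels that way and
appends unvoted labels of the disease with vote count 0. A
single-syndrome disease gets a degenerate constant model. No stacking
weights are trained; the integration is the vote itself.

Evaluation is stratified 5-fold cross-validation per disease, reporting
one accuracy per base kind plus the integrated vote (folds are reduced,
with a warning, when the smallest syndrome class is smaller than 5).

## Preprocessing and resampling

Full-width code points (U+FF01–U+FF5E and the ideographic space) fold to
their half-width forms; the mapping is 1:1 per code point, so character
spans survive normalization. Non-text placeholders (`[[...]]`) are
stripped. Freestyle text splits into predefined sections on `[name]`
markers, with a `preamble` section for leading text and concatenation
(logged) on duplicated markers.

Quality control discards a note iff it lacks an admission or discharge
page, a checked field (default: disease, sex, age) differs between the
two pages, or the chief complaint lacks the standard
symptom-with-duration form. The first failing rule is the recorded
reason.

Class balancing operates on vectorized training records only —
interpolating raw text is ill-defined — and never touches validation or
test data. Classes above target are down-sampled uniformly without
replacement; classes below target gain synthetic-minority interpolants
x + u·(neighbor − x), u ~ U(0,1), neighbor among the k = 5 nearest
same-class points (so interpolants stay inside the class's convex
support). The 8:1:1 partition gives validation and test exactly
⌊N/10⌋ ids each (22,984 notes → 2,298), remainder to train, stratified
by disease via largest-remainder allocation, fully seeded. Where the
disease classifier's token sequences need balancing, plain resampling
(with replacement below target) substitutes for interpolation.

## Synthetic corpus

The generator emulates the statistical structure the pipeline assumes:
nine predefined sections per note; gold spans for five entity types;
duration tokens adjacent to their symptoms; a many-to-many ontology
(sharing of a syndrome between diseases is forced if sampling misses
it); severe class imbalance on request (e.g. 2180/1913/109/584); synonym
variants resolved by the shipped dictionary; full-width renderings of
whole tokens (length-preserving, so spans stay valid); and exactly the
requested counts of the three QC violation kinds, at most one per note.
Identical configs produce byte-identical corpus files.

Each disease owns core symptoms shared by its syndromes plus signature
symptoms per (disease, syndrome) pair; with synonym noise 0 the symptom
lexica of different diseases are disjoint. This separability dial is the
basis of the parameter-recovery tests: a system that implements every
stage correctly must recover diseases and syndromes nearly perfectly on
a separable corpus, so those tests certify the plumbing and the
learning dynamics — not clinical performance. What the generator does
not emulate: real Chinese prose and segmentation ambiguity, annotation
disagreement, overlapping symptom vocabularies across diseases,
label noise, and corpus-scale vocabulary (the reference system's
149,076-word pretrained embedding is out of scope; embeddings here are
trained from scratch). Reported hospital-corpus accuracies (disease
83.9/92.4/95.7% top-1/3/5, system 80.5/91.6/94.2%, mean syndrome
accuracy ≈ 0.91) are therefore context, not targets, for the synthetic
runs.

## Evaluation

Top-k accuracy is the fraction of cases whose gold label appears among
the k highest-ranked predictions; by construction it is non-decreasing
in k. System-level accuracy demands disease and syndrome simultaneously
correct; for k > 1 the gold disease's syndrome model is consulted only
if the gold disease is within the top-k, which makes system top-k ≤
disease top-k provable rather than merely observed. The recovery suite
trains on a separable corpus of 8 diseases, ~20 syndromes and 200 notes
per class — large enough that every syndrome class supports 5-fold CV,
small enough to run on one CPU in about two minutes (NER fitting is
capped at 400 notes, which is past its learning-curve plateau on this
corpus) — and requires NER span F1 ≥ 0.95, disease top-1 ≥ 0.9, every
base learner ≥ 0.9 with the integrated vote within 0.02 of each, and
system top-1 ≥ 0.8.

## Known limitations

- The tagger's encoder is a compact tanh recurrent network, not a
  large gated one; on long real-world sentences with open vocabulary it
  would need the character features and more capacity.
- SVC confidences are rank-preserving transforms of margins, not
  calibrated probabilities; the vote's confidence tie-break inherits
  that.
- The per-disease design cannot predict syndromes for a disease absent
  from training (`predict_syndrome` raises instead of guessing).
- Balancing by interpolation assumes feature vectors live in a space
  where convex combinations are meaningful; for heavily sparse vectors
  the interpolants densify minority classes slightly.
- System top-k for k > 1 scores the gold disease's model; an
  application would instead show the user one syndrome list per
  candidate disease.
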