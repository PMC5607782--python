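# Methods

## Model

Publishing is modeled as a two-player game over a corpus `X` of `n` tokens,
each with a binary sensitivity label `S(x)` (1 = sensitive identifier, e.g.
a personal name).  The token is the unit of everything: multi-word names
are consecutive sensitive tokens, and all counting (TP/FP/TN/FN) is
per-instance.  Redaction replaces a token's surface with a placeholder
(`[NAME]` by default) rather than deleting it, so document structure and
token counts are preserved, and downstream consumers — including the
simulated attacker — see the placeholder, never the original surface.

The publisher picks an ordered classifier set `H` from a hypothesis class
`ℋ` assumed common knowledge, publishes `P(H) = X \ X₁(H)` (everything no
member flags), and incurs `T(H) = L·FN(H) + C·FP(H)`.  `FN(H)` intersects
over members (a sensitive token survives only if every member misses it);
`FP(H)` unions (a clean token is lost if any member flags it).  The
attacker labels a fraction of `P` (omniscient labeling — inspection is an
oracle lookup against the truth), picks the most accurate classifier in
`ℋ` on that holdout, ranks the remaining tokens predicted-positives first,
and inspects the top `B`.

### The greedy loop

Each iteration trains a candidate on the residual training set `D_{k−1}`
(tokens not yet flagged), computes its confusion counts there, and stops
iff `ΔT = C·FP − L·TP ≥ 0`; otherwise the candidate joins `H` and its
predicted positives are removed.  Three accounting decisions:

* The stopping rule is evaluated with true labels on residual *training*
  data; its transfer to held-out data is exactly what the finite-sample
  bounds quantify.
* The stop-triggering candidate is **not** a member of `H`.
* "Removal" is set-subtraction from the training set, not text deletion:
  surviving tokens keep their original document context for feature
  extraction, and removed neighbors enter sequence decoding as
  known-positive history states.

Termination: every accepted classifier removes at least one true positive
(otherwise `ΔT ≥ 0`), so at most `|X|` classifiers are accepted; one final
candidate — possibly trained on an empty residual, where all counts are 0
by definition — triggers the stop.  The trained-candidate count is thus at
most `|X| + 1`, the accepted count at most `|X|`.

### Retraining and seeding

Each iteration retrains from scratch (no warm start) with a per-iteration
seed `seed + k`, so a fit is a pure function of (corpus, params, learner,
seed).  In cross-validated evaluation, `H` is learned on the training folds
and applied member-by-member, in training order, to the held-out fold.

## Learners

The registry realizes `ℋ` with scikit-learn:

* `memm` — a maximum-entropy Markov sequence tagger: logistic regression
  (liblinear) over orthographic features plus a previous-label history
  feature, trained with gold history (teacher forcing) and decoded greedily
  left-to-right feeding its own predictions.  Since the model is linear,
  the history contributes one scalar weight per previous state, so decoding
  costs one vectorized scoring pass plus O(1) per token.
* `svm` — the same sequence construction over a linear SVM.
* `adaboost` — boosted depth-1 decision stumps, no history features.
* `ensemble` — two-stage: the sequence tagger for recall, then a linear
  SVM trained on its predicted positives to prune false positives.
* `lookup` — per-surface cost-weighted majority vote; trivially fast and
  exactly monotone in the class-weight ratio, used for cheap baselines and
  property tests.
* `constant0` — never predicts positive; the degenerate publisher.

Features per token: surface and lowercase identity, character-shape
pattern, digit/punctuation/title flags, prefixes and suffixes of length
1–3, and the surfaces at window offsets −2…+2 (explicit `<PAD>` at document
boundaries).  Part-of-speech is approximated by these orthographic and
affix cues; a hook accepts precomputed POS columns, keeping the package
dependency-free of external taggers.  Single-class training data yields
the constant classifier of that class rather than an error.

Cost-sensitive training weights the positive class by `L/C` (class weights
for the linear models, sample weights for boosting).  Plain accuracy
training (`ratio = 1`) is what the greedy loop uses; the cost-sensitive
mode exists for the single-classifier baselines it is compared against.

Best-of-registry selection splits the provided documents 75/25 (seeded),
trains every learner on the larger part, scores accuracy on the smaller,
and returns the winner (ties break by registry order).  The returned
handle is the one trained on the split, matching what the selection
accuracy actually measured.

## Attacker scoring

Within a rank class the pool is exchangeable, so utilities are computed in
closed form by default: with attacker counts (TP, FP, TN, FN) on the
inspectable pool and budget `B`,

* `B ≤ TP+FP`:  `U*_A = L·B·TP/(TP+FP)`
* `B > TP+FP`:  `U*_A = L·(TP + (B−TP−FP)·FN/(FN+TN))`
* baseline:     `U_A = L·B·(TP+FN)/(TP+FP+TN+FN)`.

Expectation scoring makes small-fixture results exact and matches the
accounting of the closed-form bounds; a `sampled` mode draws the actual
random order instead, and a test verifies the Monte-Carlo realized utility
agrees with the expectation within three standard errors.  The attacker's
labeled holdout is excluded from the inspectable pool (those labels are
already known); `train_fraction = 0` selects the idealized attacker that
trains on all of `P` and is scored over all of `P`, which is the regime of
the worked 26-token example.  Ties within a rank class are broken by
document order for reproducibility.

## Bound calculators

All guarantees are reported as real numbers (they bound count-valued
quantities but are themselves real-valued, so no flooring is applied) with
their preconditions flagged rather than silently
assumed: the ranking condition `TP_A·TN_A ≥ FP_A·FN_A`, the surplus-budget
regime `B ≥ TP_A + FP_A`, and the deviation-term validity
`λ(δ,m) < (1+1/p)·q·L/C`.  `log` in `λ` is the natural logarithm.  When
the count-ratio constants are not supplied they are estimated from data:
`p = FP̂/FN̂` and `q = TP̂/(TP̂+FN̂)` from the final training-iteration
counts, `r = TP_A/(TP_A+FN_A)` and `s = FP_A/FN_A` from attacker counts —
the recall-style normalizers are this package's estimator choice and are
carried in the report.  Note that a *finite* `p` tightens (not loosens)
the finite-sample bounds, since `1+1/p > 1` enlarges the denominator;
dominance of the finite-sample bound over the asymptotic one is guaranteed
only at the tight training-side limit (`p → ∞`, `q = 1`).

The set identities behind the stopping rule (`FN(H) = FN(H∪h) + TP(h,P(H))`
and `FP(H∪h) = FP(H) + FP(h,P(H))`) and the local-optimum characterization
are verified against brute-force set computation: exhaustively for all
(labeling, `H`, `h_A`) triples on universes up to 4 tokens, and on
thousands of randomized universes up to 20 tokens.

## Synthetic corpora

The generator emulates the statistical shape of de-identification corpora,
not their language:

* **Rarity** — a target sensitive fraction `alpha_target` (default 0.02,
  the scale of real clinical corpora, where names are ~2–5% of tokens).
  The per-slot rate is corrected for cue insertion so the realized
  fraction hits the target (within ±20% relative; a seeded test asserts
  convergence with corpus size).
* **Ambiguity** — a fraction `ambiguity_rate` (default 0.3) of the name
  vocabulary also occurs as ordinary non-sensitive tokens (the
  pronoun-vs-surname problem), occupying ~5% of background slots.  At
  rate 1 no surface-only classifier can reach zero training error; a test
  verifies this with the exhaustive per-surface lookup classifier.
* **Learnability** — with probability `context_cue_strength` (default 0.7,
  reflecting how often clinical names follow honorifics or role cues) a
  sensitive token is preceded by a cue token (`Dr.`, `Mr.`, …).  Cued or
  unambiguous names are learnable; ambiguous, uncued ones are not — which
  is precisely the "high but imperfect recall" regime the method targets.

Defaults are 500 documents × Poisson(200) tokens, name vocabulary 400,
background vocabulary 2000 under a Zipf-like rank distribution plus
function words, punctuation (~8%) and number tokens (~2%).  Vocabularies
are syllable-sampled, so the corpus is deterministic per seed (byte-
identical files, asserted).

What passing tests on this generator do **not** show: robustness to real
orthographic noise (typos, OCR), to entity types other than a single
sensitive class, to genuine part-of-speech signal, or to long-range
contextual inference attacks (correlated context words are out of scope
throughout).

## Evaluation harness

Cross-validation is document-level (tokens of one document never straddle
a fold boundary, avoiding window-feature leakage), four folds by default.
Per fold: greedy loop on the training folds → apply `H` to the held-out
fold → publish → attack at each budget → metrics (publish ratio, residual
sensitive count, expected identified-per-budget, utility ratio).
Cost-sensitive single-classifier baselines at weight `L/C` run on the same
folds.  Reports are JSON throughout; determinism of the full report under
a fixed config+seed is asserted.

## Problem sizes and numerical choices

The end-to-end study runs use the generator defaults (≈100k tokens,
four folds, the `memm` learner), which complete in a few minutes on one
CPU; unit and property tests use corpora of a few thousand tokens and the
`lookup` learner where the property under test is learner-agnostic
(termination, monotone trends), keeping the suite fast without touching
the study conditions.  Tolerances: closed-form quantities are asserted to
1e−9–1e−12; stochastic comparisons use three standard errors; trend
assertions over seeded sweeps require weak monotonicity.  Degenerate
inputs are defined, not special-cased: empty corpora publish nothing,
empty subsets have all-zero counts, a zero baseline utility makes the
ratio an explicit error.

## Known limitations

* The sequence learners are linear taggers with one-step history, not
  CRFs; they realize the same interface and the qualitative regime (high
  recall, small residual), but no claim is made about matching any
  specific published de-identification system's accuracy.
* The attacker model is deliberately pessimistic (omniscient labels on its
  holdout, shared hypothesis class); real attackers are weaker, so the
  computed risks are conservative.
* The VC dimension `υ` is a user input; the package does not derive it for
  concrete learner families.
* Guarantees hold at the training-side local optimum; train/test
  divergence is surfaced by the precondition flags and the finite-sample
  terms, not hidden.
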