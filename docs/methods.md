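# Methods

## Problem and model

`girem` infers a gene–gene functional-relation network from literature
co-occurrence. The unit of evidence is a *binary per-unit status*: within
one text unit (an abstract or a sentence) an entity either is or is not
mentioned, regardless of multiplicity. Three levels of units are tallied:

* **A** — abstracts;
* **S** — sentences;
* **SE** — the subset of sentence-level co-occurrences whose connective
  pattern marks the two mentions as semantically related.

For a candidate pair (g_x, g_y) the co-occurrence ratio at level α is

    W = Σ co(g_x, g_y) / (Σ so(g_x) + Σ so(g_y)),

summed over the units of α. Because co ≤ min(so_x, so_y) ≤ (so_x+so_y)/2,
every weight lies in [0, 0.5], with 0.5 attained exactly when the two
entities always co-occur. Nine such ratios form the feature vector:
gene–gene at A/S/SE (W1–W3), g_x against the GO-term group of g_y at
A/S/SE (W4–W6), and the mirror direction (W7–W9). A *GO-group occurrence*
for gene g is a mention of any GO term (name or accession) annotated to
g; one GO-term mention therefore credits every gene it annotates.

Candidate pairs are the pairs with at least one abstract-level
co-occurrence — the pairs actually found together in the literature. An
all-pairs universe would be quadratic and its extra rows all-zero.

### Semantic verdicts

Verdicts are computed from the word tokens strictly between the two
mention spans, which keeps them pairwise-local and makes the verdict a
pure function of the inter-mention text:

1. any contrasting conjunction present → **unrelated** (contrast beats a
   co-present linking phrase: in "geneA binds with geneB but not with
   geneC", A–B is related and A–C is not);
2. otherwise any similarity conjunction or linking phrase → **related**;
3. otherwise → **unmarked** (counts at S but not at SE).

The shipped connective sets (in `src/girem/data/rules.json`) are
deliberately small and frozen for reproducibility; they are a
configurable input, not a claim of completeness. The linking set includes
the bare token "as", which buys recall on constructions like "acts as a
scaffold for" at a known cost in precision; users mining real text may
want to drop it.

Mentions come from maximal case-insensitive dictionary matching over
token sequences, longest match first. Gene symbols are matched verbatim
(stemming symbols would create false hits — "CAT" the gene vs "catalog");
GO term names are matched with a light plural stripper on both sides. No
synonym or abbreviation resolution is attempted, and relations never
cross sentence boundaries — both are real recall limitations on genuine
abstracts.

### Solo counts at the semantic level

A lone mention has no partner to be "related" to, so SE-level solo counts
are undefined by the counting model. SE-level weights therefore reuse the
sentence-level solo counts in their denominators. Since SE numerators are
a subset of S numerators over a shared denominator, W3 ≤ W2 (and W6 ≤ W5,
W9 ≤ W8) by construction. A zero denominator — no evidence for either
entity — yields weight 0.

## Labeling

Given a benchmark network of experimentally supported edges: a candidate
pair that is an edge gets class 1; a pair that is not an edge *and* whose
genes share no benchmark neighbor gets class 0; everything else stays
unlabeled and is only scored at prediction time. Declaring non-relation
is the delicate part: the no-common-neighbor condition restricts class 0
to pairs with the least circumstantial evidence. A gene absent from the
benchmark vertex set has an empty neighbor set, so its pairs satisfy the
condition vacuously and are labeled 0 — "never observed interacting" is
treated as negative evidence, not as unknown. This is deliberate and
debatable; swap in a curated negative set if you have one.

## Classifier

Related pairs are rare among candidate pairs, but training uses a
balanced subsample. Each training case is weighted by the ratio of its
class proportion in the population (Q) to that in the sample (H):
w = Q₁/H₁ for events, (1−Q₁)/(1−H₁) for non-events. With a balanced
sample from a rare-event population this down-weights events and keeps
the fitted intercept anchored to the population base rate instead of the
artificial 50/50 of the sample. By default Q₁ is estimated as the event
rate among all labeled pairs and H₁ is the training-sample event rate.

The objective is the weighted ridge-penalized log-likelihood

    lnL(β) = Σ w_i [ y_i x_i β − ln(1+e^{x_i β}) ] − (λ/2)‖β‖²,

maximized by Newton–Raphson with step-halving (tolerance 1e−8 on the
gradient max-norm, at most 100 iterations). For λ > 0 the objective is
strictly concave, so the optimum is unique. The intercept is the first
coefficient and is *not* penalized by default — penalizing it would bias
the base rate; `penalize_intercept=True` restores the literal
all-coefficients penalty. The penalty multiplies the *summed* (not mean)
log-likelihood, so useful λ values scale with the training-set size.

Predicted classes follow the 0.5 rule, with ties at exactly 0.5 assigned
to class 0.

### Rare-event bias correction

A post-hoc correction subtracts a weighted-least-squares estimate of the
second-order score bias from the estimate:

    bias = (XᵀVX)⁻¹ XᵀV ξ,   ξ_i = ½ Q_ii [(1+w₁) p̂_i − w₁],

where V = diag(w_i p̂_i(1−p̂_i)), Q_ii is the leverage of case i under
(XᵀVX)⁻¹, and w₁ is the event weight. With unit weights this reduces to
the classical small-sample bias of logistic regression. The correction is
an asymptotic term and only meaningful as a small perturbation of a
finite interior optimum: under (quasi-)separated data the information
matrix degenerates and the formula produces garbage. The implementation
therefore skips the correction — with a warning, and
`bias_corrected=False` on the returned model — when the unpenalized
information matrix is ill-conditioned (condition number above 1e8) or the
correction exceeds half the coefficient norm. The flag
`bias_correction=False` disables it entirely.

## λ selection and evaluation

The ridge strength is chosen from a grid by balanced bootstrap
resampling: per λ, repeatedly draw a balanced training sample with
replacement, fit, and measure both per-class accuracies on the
out-of-bag labeled rows; the winner maximizes the *minimum* of the two
mean class accuracies (the most conservative reading of "accurate on both
classes"), with ties broken toward the smaller λ. The identical draw
sequence is replayed for every grid value, so the comparison is paired
and deterministic given the seed.

Reported metrics are the confusion-matrix identities (recall = TP/(TP+FN),
precision = TP/(TP+FP), F as their harmonic mean, TNR = TN/(TN+FP);
per-class accuracies are recall and TNR). The ROC sweeps every distinct
predicted probability as a cutoff and the AUC is the trapezoidal area,
which equals the Mann–Whitney statistic with ties counted one half.

Headline metrics are computed by *cross-fitting*: the labeled rows are
split into five folds and each fold is scored by a model fitted on a
balanced draw from the remaining folds, so no pair is ever scored by a
model that saw it. In-sample scoring measurably flatters a near-separable
fit (on null-signal corpora it inflates the AUC several points above
chance); cross-fitting removes that bias while still using every labeled
row.

## Synthetic data

The generator plants a ground-truth interaction network (Bernoulli edges
at a configurable density, default 0.12 over 30 genes) and writes
abstracts of templated sentences. Each abstract samples 5 genes; each
pair among them co-occurs in a sentence with probability 0.6 if it is a
planted edge and 0.05 otherwise. Edge co-mentions use similarity/linking
connectives; non-edge co-mentions use a contrasting conjunction with
probability 0.9 and otherwise the *same* positive templates — so setting
the two co-occurrence rates equal and the contrast rate to zero yields a
corpus carrying no signal at all, which the pipeline should (and does)
score at chance AUC. A co-mention sentence carries a follow-up sentence
joining the first gene to a GO term of its partner with probability 0.3,
feeding W4–W9; the follow-up inherits the pair's connective mode so it
leaks no extra label information. Genes not co-mentioned in an abstract
get solo sentences. The benchmark handed to labeling is the truth network
itself, so label noise is zero by default.

These defaults — 30 genes, 500 abstracts, 0.6/0.05 co-occurrence rates —
are the study conditions of the end-to-end tests. What passing them
shows: the counting, weighting and classification machinery recovers a
planted network from clean, template-generated text, and invents nothing
under a null. What it does not show: robustness to real MEDLINE prose,
synonyms, abbreviations, cross-sentence relations or noisy benchmarks —
the generator emulates none of these.

## Numerical and design choices

* Canonical pair order: lexicographically smaller gene id first,
  everywhere; W4–W6 vs W7–W9 are defined relative to that order.
* Mentions are deduplicated per entity per sentence (first occurrence
  kept) before verdicts, matching the binary per-unit statuses.
* The sentence splitter is rule-based (terminal punctuation, an
  abbreviation allowlist, and a requirement that the next sentence start
  with an upper-case letter, digit or bracket) — deterministic and
  dependency-free, tuned for abstract-style prose.
* |SE| is the number of sentences containing at least one related
  verdict; it is reported for transparency but no weight depends on it.
* Newton steps fall back to least-squares solves if the Hessian is
  singular; non-convergence returns the last iterate with a warning
  rather than raising, since separable balanced draws are routine at
  λ = 0.
* All randomness flows from `numpy.random.default_rng(seed)`; outputs
  are byte-identical across repeats, floats are serialized with
  shortest round-trip representation.
* Problem sizes in the test suite (corpora of 30–500 abstracts, grids of
  four λ values, 10 bootstrap rounds) are chosen so the whole suite runs
  in seconds while still exercising every code path at realistic
  signal-to-noise; the statistical conclusions they support are stated
  above.

## Known limitations

* Primary gene symbols only; no synonym/abbreviation resolution.
* Flat-token connective rules; no dependency parsing, so long-range or
  syntactically embedded relations are missed, and coordination ("and")
  is treated as relational evidence even when it is merely enumerative.
* The no-common-neighbor negative rule inherits benchmark incompleteness:
  missing benchmark edges can both mislabel true positives as 0 and leak
  them into the unlabeled pool.
* The λ scale is tied to the summed likelihood and hence to the training
  size; tune λ per training-set size rather than reusing values across
  sizes.
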