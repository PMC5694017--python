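# girem

Gene–gene relation mining from biomedical abstracts with rare-event
weighted logistic regression.

`girem` predicts functionally related gene pairs from literature
co-occurrence. Given an abstract corpus, a gene lexicon, a Gene Ontology
(GO) annotation table and a benchmark interaction network, it

1. recognises gene and GO-term mentions in every sentence (dictionary
   matching, longest match wins) and classifies each within-sentence
   mention pair as semantically **related**, **unrelated** or **unmarked**
   from the connective tokens between them — a contrasting conjunction
   (*but*, *whereas*, ...) marks a pair unrelated and beats everything
   else; a similarity conjunction (*and*, *or*, ...) or linking phrase
   (*binds to*, *interacts with*, ...) marks it related;
2. tallies binary solo (`so`) and co-occurrence (`co`) statuses at three
   text levels α ∈ {A (abstract), S (sentence), SE (semantically related
   sentence)} and represents each candidate pair (g_x, g_y) by nine ratio
   weights

   W_N = Σ_i co(g_x, g_y)_i / (Σ_i so(g_x)_i + Σ_i so(g_y)_i)

   — W1–W3 for the direct gene–gene co-occurrence at A/S/SE, W4–W6 for
   g_x with the GO-term group of g_y, and W7–W9 for the mirror direction.
   Every weight lies in [0, 0.5];
3. labels pairs from the benchmark (edge ⇒ class 1; non-edge with no
   common neighbor ⇒ class 0; everything else stays unlabeled) and fits a
   weighted, ridge-penalized logistic regression

   lnL(β) = Σ_i w_i [ y_i x_i β − ln(1 + e^{x_i β}) ] − (λ/2)‖β‖²

   with per-class rare-event weights w_i = Q/H (population vs sample
   class proportions), Newton–Raphson with step-halving, an optional
   post-hoc rare-event bias correction, and bootstrap selection of λ;
4. predicts P(related) for every candidate pair (class 1 iff p > 0.5) and
   assembles the predicted relation network.

It is aimed at systems-biology work where experimentally verified
interactions are scarce (rare events) relative to the number of candidate
pairs found in the literature.

## Worked example

Feature extraction on a two-abstract corpus:

```python
from girem import AbstractDoc, GeneLexicon, GoAnnotationTable
from girem.features import tally, build_feature_matrix

lexicon = GeneLexicon(entries={"G1": "TP53", "G2": "BRCA1"})
go = GoAnnotationTable(records={"G2": frozenset({("GO:0006281", "DNA repair")})})
corpus = [
    AbstractDoc("pmid1", "TP53 and BRCA1 interact. TP53 induces DNA repair genes."),
    AbstractDoc("pmid2", "TP53 was assayed alone."),
]
t = tally(corpus, lexicon, go)
for row in build_feature_matrix(t, go):
    print(row.gene_a, row.gene_b, [round(w, 4) for w in row.w])
```

prints

```
G1 G2 [0.3333, 0.25, 0.25, 0.3333, 0.25, 0.0, 0.0, 0.0, 0.0]
```

Reading the numbers: TP53 appears in 2 abstracts and BRCA1 in 1, they
share 1, so W1 = 1/(2+1) = 0.3333; at the sentence level TP53 has 3 solo
sentences and BRCA1 has 1, with one shared sentence whose "and" marks the
pair related, so W2 = W3 = 1/4. "DNA repair" is a GO term of BRCA1, so
TP53 co-occurring with it gives W4 = 1/3 and W5 = 1/4; the connective
between TP53 and "DNA repair" in that sentence is the unmarked "induces",
so the semantic-level W6 is 0. TP53 has no GO annotations, hence
W7–W9 = 0.

The full pipeline runs from the command line. With no input files it
generates a synthetic corpus with a planted interaction network (30
genes, 500 abstracts by default) and mines it back:

```bash
girem run-all --outdir out --seed 7
```

```json
{
  "abstracts": 500,
  "best_lambda": 0.0,
  "candidate_pairs": 435,
  "labels": {"negative": 289, "positive": 46, "unlabeled": 100},
  "metrics": {
    "accuracy_class0": 1.0,
    "accuracy_class1": 0.9782608695652174,
    "auc": 0.9996238904769068,
    ...
  },
  "network_edges": 50,
  "seed": 7,
  "sentences": 2281
}
```

435 candidate pairs were featurized; 46 are benchmark edges (class 1),
289 share no benchmark neighbor (class 0), 100 stay unlabeled. The
cross-fitted classifier recovers the planted network almost perfectly
(AUC 0.9996; one false negative). Each stage is also available as its own
subcommand (`simulate`, `extract`, `features`, `label`, `tune`, `train`,
`predict`, `evaluate`, `network`) over plain TSV/JSON-lines files; run
`girem --help`.

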