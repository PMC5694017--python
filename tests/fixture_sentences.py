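"""Hand-labeled fixture sentences for the connective-rule classifier.

Each record names a sentence, an ordered mention pair (by surface form) and
the verdict a human annotator assigns under the stated rules: a contrasting
conjunction strictly between the mentions makes the pair unrelated
(contrast beats everything); otherwise a similarity conjunction or linking
phrase makes it related; otherwise it is unmarked.  Labels were assigned by
hand from the sentence text, independently of the classifier.

Entities: geneA/geneB/geneC are gene symbols; "apoptotic process" is a GO
term name annotated to geneB in the toy tables.
"""

# (sentence, first mention surface form, second mention surface form, verdict)
LABELED_PAIRS: list[tuple[str, str, str, str]] = [
    # worked example: linking phrase relates A-B, the contrast cuts off A-C
    ("geneA binds with geneB but not with geneC", "geneA", "geneB", "related"),
    ("geneA binds with geneB but not with geneC", "geneA", "geneC", "unrelated"),
    ("geneA binds with geneB but not with geneC", "geneB", "geneC", "unrelated"),
    # similarity conjunctions
    ("geneA and geneB are coexpressed", "geneA", "geneB", "related"),
    ("geneA or geneB may compensate for the loss", "geneA", "geneB", "related"),
    ("geneA as well as geneB were induced", "geneA", "geneB", "related"),
    ("geneA and geneB as well as geneC form a complex", "geneA", "geneB", "related"),
    ("geneA and geneB as well as geneC form a complex", "geneA", "geneC", "related"),
    ("geneA and geneB as well as geneC form a complex", "geneB", "geneC", "related"),
    # linking phrases
    ("geneA interacts with geneB in vivo", "geneA", "geneB", "related"),
    ("geneA binds to geneB", "geneA", "geneB", "related"),
    ("geneA interacted with geneB in yeast two-hybrid assays", "geneA", "geneB", "related"),
    ("geneA associates with geneB during mitosis", "geneA", "geneB", "related"),
    ("geneA associated with geneB in co-immunoprecipitation", "geneA", "geneB", "related"),
    ("geneA was induced and as a result geneB was activated", "geneA", "geneB", "related"),
    ("geneA acts as a scaffold for geneB", "geneA", "geneB", "related"),
    ("geneA binds to the promoter and geneB binds to the enhancer", "geneA", "geneB", "related"),
    # contrasting conjunctions
    ("geneA is induced, whereas geneB is suppressed", "geneA", "geneB", "unrelated"),
    ("geneA was elevated but geneB was reduced", "geneA", "geneB", "unrelated"),
    ("geneA but not geneB rescued the phenotype", "geneA", "geneB", "unrelated"),
    ("geneA suppresses tumor growth while geneB promotes it", "geneA", "geneB", "unrelated"),
    ("geneA is silenced although geneB remains active", "geneA", "geneB", "unrelated"),
    ("geneA phosphorylates substrates however geneB is unaffected", "geneA", "geneB", "unrelated"),
    ("geneA was overexpressed however geneB levels were unchanged", "geneA", "geneB", "unrelated"),
    ("Loss of geneA but retention of geneB was observed", "geneA", "geneB", "unrelated"),
    ("geneA whereas geneB", "geneA", "geneB", "unrelated"),
    # contrast overrides a linking phrase between the mentions
    ("geneA interacts with geneB but fails to bind geneC", "geneA", "geneB", "related"),
    ("geneA interacts with geneB but fails to bind geneC", "geneA", "geneC", "unrelated"),
    ("geneA interacts with geneB but fails to bind geneC", "geneB", "geneC", "unrelated"),
    ("geneA interacts with geneB although geneC is required", "geneA", "geneC", "unrelated"),
    ("geneA activates geneB whereas geneC represses it", "geneA", "geneC", "unrelated"),
    ("geneA activates geneB whereas geneC represses it", "geneB", "geneC", "unrelated"),
    # no connective between the mentions -> unmarked
    ("geneA regulates geneB", "geneA", "geneB", "unmarked"),
    ("Expression of geneA correlates with that of geneB", "geneA", "geneB", "unmarked"),
    ("Mutations in geneA impair binding of geneB", "geneA", "geneB", "unmarked"),
    ("geneA activates geneB whereas geneC represses it", "geneA", "geneB", "unmarked"),
    ("The complex of geneA with geneB dissociates", "geneA", "geneB", "unmarked"),
    ("geneA is unrelated to geneB", "geneA", "geneB", "unmarked"),
    ("Neither geneA nor geneB was expressed", "geneA", "geneB", "unmarked"),
    ("geneA geneB fusion transcript", "geneA", "geneB", "unmarked"),
    ("geneA functions redundantly with geneB or geneC", "geneA", "geneB", "unmarked"),
    ("geneA functions redundantly with geneB or geneC", "geneA", "geneC", "related"),
    ("geneA functions redundantly with geneB or geneC", "geneB", "geneC", "related"),
    # gene - GO-term pairs follow the same rules
    ("geneA interacts with apoptotic process regulators", "geneA", "apoptotic process", "related"),
    ("geneA declined whereas apoptotic process activity rose", "geneA", "apoptotic process", "unrelated"),
    ("geneA modulates apoptotic process kinetics", "geneA", "apoptotic process", "unmarked"),
]
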