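"""Classify microglia morphologies with supervised UMAP + HDBSCAN voting.

Renders a labelled 7-class benchmark (20 cells per class), cross-validates
the classifier and prints the confusion matrix.  Held-out cells are
projected through the learned embedding, clustered together with the
training cells, and inherit their cluster's majority annotation.
"""

from microglia_morph import classification, synthetic as syn

table = syn.morphology_feature_table(n_per_class=20, seed=11)
annotations = table["class_name"]

result = classification.cross_validate(table, annotations, k=3, seed=5)
print(f"3-fold CV on {len(table)} rendered cells")
print(f"accuracy over assigned cells: {result.accuracy:.1%}")
print(f"unassigned fraction:          {result.unassigned_fraction:.1%}")
print("\nconfusion matrix (rows = true class, last column = unassigned):")
print(result.confusion.to_string())
print("\nHigh accuracy here shows the derived shape features separate the"
      "\nseven archetypes; accuracy on real cultures depends on annotation"
      "\nquality and class overlap.")
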