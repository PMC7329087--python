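"""Rank samples by the criterion and build the six best/worst phylograms.

Each phylogram clusters the dataset's feature columns by normalized
compression distance over one ranked subset; features that co-vary with
the criterion sit close to it in the tree.
"""

from fsopa.model import build_model, model_object_columns
from fsopa.sampling import SUBSET_LABELS, ss_sample
from fsopa.synth import SynthSpec, generate_table

table, truth, _ = generate_table(SynthSpec(n=800, seed=7, n_date=0, n_code=0))
objects = model_object_columns(table, exclude=["event"])

subsets = ss_sample(table, "los", direction="minimize")
print(f"ranked {subsets.n_ranked} rows; subset sizes:",
      {label: len(subsets[label]) for label in SUBSET_LABELS})

for label in ("B2C", "W2C"):
    tree = build_model(table, subsets[label], objects=objects)
    print(f"{label}: {tree.n_leaves} leaves, modularity {tree.modularity:.3f}")
print("B2C Newick:", build_model(table, subsets["B2C"], objects=objects)
      .to_newick()[:100], "...")
# The half of the cohort with the shortest stays (B2C) and the half with
# the longest (W2C) get their own trees; the sensitivity stage compares them.
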