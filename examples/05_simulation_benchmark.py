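"""A miniature precision/recall benchmark of the retrieval protocol.

Simulates families along balanced trees whose root-to-target path is
elongated by increasing factors, then retrieves each family's fast-evolving
side using its slow side as seeds, pooling all families as the search
space. Uses a small design so it runs in seconds; the full scaled design is
exercised by scripts/acceptance.py.
"""

from divmine import generate_design, realize_all, run_benchmark
from divmine.simbench import scores_frame, summarize_scores

families = generate_design(n_leaves=8, factors=(1.0, 4.0, 8.0), replicates=1,
                           root_length=120)
realize_all(families, master_seed=5)
print(f"{len(families)} families ({len(families) * 8} pooled sequences)")

scores, _ = run_benchmark(families, backend="blast")
frame = scores_frame(scores)
print(f"false-positive retrievals: {frame['n_false'].sum()}")
print(summarize_scores(scores).to_string(index=False))
print(
    "\nRecall is complete in the null case (factor 1) and collapses as the\n"
    "elongation factor grows; precision stays 1 wherever anything is\n"
    "retrieved - no sequence is ever pulled in from a foreign family."
)
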