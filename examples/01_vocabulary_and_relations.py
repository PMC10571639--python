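"""Load a concept vocabulary, filter to vaccine terms, classify relations.

Builds a tiny vocabulary TSV, loads it into a ConceptGraph, restricts it to
the vaccine subtree, and asks how two concepts relate in the hierarchy —
the primitive behind the hierarchy branch of the error taxonomy.
"""
from pathlib import Path
import tempfile

from vaxnorm import classify_relation, filter_vaccine_terms, load_vocabulary

TSV = """id\tlabel\tsynonyms\tparents\tis_vaccine
V:1\tvaccine\t\t\t1
V:2\tcholera vaccine\tCV\tV:1\t1
V:3\tcholera conjugate vaccine\t\tV:2\t1
V:4\tVaxchol\tVaxchol®\tV:3\t1
A:1\timmunization assay\t\t\t0
A:2\tELISA assay\t\tA:1\t0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "vocab.tsv"
    path.write_text(TSV)
    graph = load_vocabulary(path)

print(f"loaded {len(graph)} concepts, roots = {sorted(graph.roots)}")

vaccines = filter_vaccine_terms(graph, subtree_roots=["V:1"])
print(f"vaccine subtree keeps {len(vaccines)} of {len(graph)} concepts")

for gold, pred in [("V:3", "V:3"), ("V:3", "V:2"), ("V:4", "V:2"), ("V:4", "V:1"), ("V:2", "ZZZ")]:
    print(f"gold={gold} pred={pred}: {classify_relation(graph, gold, pred)}")

# exact        → the prediction is the gold concept
# parent_child → one is_a edge apart (e.g. conjugate vaccine vs cholera vaccine)
# ancestor_descendant → exactly two levels apart; semantic → more than two
# oov          → the predicted id is not in the vocabulary at all
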