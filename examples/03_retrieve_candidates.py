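"""Rank candidate concepts for a mention with the character n-gram encoder.

Every concept label and synonym is embedded as a unit TF-IDF vector of
character 3-grams; a mention is mapped to the concepts with the highest
cosine similarity (max-pooled over each concept's names).
"""
from vaxnorm import build_index, char_ngram_backend, retrieve
from vaxnorm.fixtures import make_ontology

graph = make_ontology(n_vaccine=40, n_distractor=10, seed=7)
names = [name for _, name in graph.iter_names()]
backend = char_ngram_backend(names, ngram_range=(3, 3))
index = build_index(graph, backend)
print(f"indexed {len(index.names)} name entries, dimension {backend.dimension}")

some_label = graph[sorted(graph)[9]].label
for mention in (some_label, f"{some_label} Placebo 0.5 mL", some_label.upper()):
    out = retrieve(mention, index, backend, k=3)
    print(f"\nmention: {mention!r}")
    for c in out.candidates:
        print(f"  #{c.rank}  {c.concept_id}  cos={c.score:.3f}  ({graph[c.concept_id].label})")

# An exact label scores cosine 1.0 at rank 1; placebo/dose suffixes lower the
# cosine but usually keep the right concept on top; case never matters.
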