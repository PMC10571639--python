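"""Mine vaccine mentions from a synthetic registry interventions table.

Generates a small ontology and interventions table, runs the two selection
queries (vocabulary substring + 'vaccine' keyword, both restricted to rows
typed Biological), and prints the PRISMA-style stage counts.
"""
from vaxnorm import build_corpus, emit_sql
from vaxnorm.extraction import InterventionRecord
from vaxnorm.fixtures import NoiseConfig, make_interventions, make_mentions, make_ontology

graph = make_ontology(n_vaccine=30, n_distractor=10, seed=42)
entries, _ = make_mentions(graph, 40, NoiseConfig(seed=42))
table = make_interventions(entries, n_background=80, seed=42)
records = [
    InterventionRecord(int(r.id), r.nct_id, r.intervention_type, r.name)
    for r in table.itertuples(index=False)
]

mentions, report = build_corpus(records, graph)
print(f"rows total        : {report.n_total}")
print(f"typed Biological  : {report.n_biological}")
print(f"vocabulary query  : {report.n_query1}")   # name contains a concept name
print(f"keyword query     : {report.n_query2}")   # name contains 'vaccine'
print(f"union of queries  : {report.n_union}")
print(f"unique mentions   : {report.n_unique}")   # after case/whitespace dedupe
print("\nfirst mined mentions:")
for row in mentions[:5]:
    print(f"  {row.nct_id}  {row.mention}")

q1, _q2 = emit_sql(graph)
print(f"\nquery 1 rendered for a live database ({q1.count('position')} name clauses)")
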