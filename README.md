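# vaxnorm

Vaccine names in clinical-trial registries are free text: the same product
appears as a trade name, an abbreviation, a generic description with dose
and lot tokens, or a "X Placebo" arm that should map to the vaccine X
itself.  `vaxnorm` is a toolkit for **medical concept normalization (MCN)**
of such mentions against a vaccine ontology: it mines candidate mentions
from an interventions table, ranks ontology concepts for each mention with
pluggable text encoders, fuses several rankers with weighted ensemble
metrics plus a string-matching promotion rule, and evaluates with Top-n
accuracy and an ontology-aware error taxonomy.

It is aimed at biomedical NLP practitioners and ontology curators who need
a reproducible, download-free harness for vaccine-name normalization:
every component works out of the box on deterministic synthetic data that
mimics the structure of a vaccine ontology and a trial-registry
interventions table, and externally trained sentence encoders can be
plugged in through a one-method contract.

## Method

**Candidate generation.** Each concept name (label and every synonym) is
embedded as a unit vector; a mention *m* is scored against concept *c* by

    s(m, c) = max over names x of c of cos(e(m), e(x))

and the top-K concepts form one model's candidate list.  The shipped
encoder `e` is a TF-IDF character n-gram vectorizer fitted on the
vocabulary names — deterministic and weight-free; any stronger encoder
(e.g. a domain-tuned BERT) can be wrapped as an `EncoderBackend`.

**Ensemble fusion.** Given per-model candidate lists and non-negative
weights w_m, the fused score of concept c is Σ_m w_m · s_m(c), where
s_m(c) is the raw cosine (`score`), the cosine min-max rescaled to [0, 1]
within model m's top-K list (`scale`), or Borda points K − rank + 1
(`rank`); concepts absent from a model's list contribute 0.  Default
weights are proportional to each model's Top-1 accuracy on a validation
split, restricted to the best three models.

**SM-Rule.** If any concept name occurs verbatim (case-folded, ®/™
stripped) inside the mention, the concept with the longest such name is
promoted to rank 1, reordering but not rescoring — this is what maps
"AIDSVAX B/E Placebo" to "AIDSVAX B/E".

**Evaluation.** Acc@n is the fraction of mentions with a gold concept in
the top n (any-match for multi-concept gold sets).  Every rank-1 miss is
classified into an error taxonomy: out-of-vocabulary gold, multi-concept
mentions, disambiguation (gold present at rank 2..K), hierarchy errors
from the concept graph (parent–child at is_a distance 1,
ancestor–descendant at distance 2, sibling via a shared parent),
linguistic heuristics (abbreviation, spelling, stemming, dose noise), and
a residual `semantic` class for deeper or unrelated confusions.

## Worked example

```bash
python examples/05_evaluate_with_error_taxonomy.py
```

runs the full pipeline (synthetic ontology of 100 concepts → 200 noisy
mentions → extraction → two char-n-gram backends → scaled-score ensemble →
SM-Rule → evaluation) and prints:

```
Model                   Acc@1  Acc@2  Acc@3  Acc@4  Acc@5  Acc@6  Acc@7  Acc@8  Acc@9  Acc@10
ensemble+scale+sm-rule  87.0   89.0   89.0   89.5   90.5   90.5   91.0   91.5   91.5   91.5

rank-1 misses: 26 of 200 mentions
  oov                          15
  disambiguation               8
  ner_multi_concept            1
  hierarchy_parent_child       1
  abbreviation                 1
```

Acc@1 = 87.0 means 174 of the 200 mentions are normalized to a gold
concept at rank 1.  Fifteen of the misses are out-of-vocabulary mentions —
their true concept is absent from the vocabulary, so no ranker can recover
them, which caps attainable Acc@n at 92.5 on this corpus.  The other
examples (`examples/01…04`) walk through each stage in isolation.

The same pipeline is available from the shell:

```bash
vaxnorm run --seed 1 --out out/
vaxnorm simulate --seed 1 --out data/          # or stage by stage
vaxnorm extract --interventions data/interventions.csv --vocab data/vocabulary.tsv --out ext/
vaxnorm index --vocab data/vocabulary.tsv --ngram 3,3 --out idx/
vaxnorm normalize --mentions data/mentions.tsv --vocab data/vocabulary.tsv --index idx/ --out preds.jsonl
vaxnorm evaluate --pred preds.jsonl --gold data/gold.tsv --vocab data/vocabulary.tsv
```

## Layout

- `src/vaxnorm/ontology.py` — concept graph, OBO/TSV loading, vaccine
  filtering, relation classification
- `src/vaxnorm/extraction.py` — the two selection queries, TF-IDF
  unique-term resolution, combine + dedupe, SQL rendering
- `src/vaxnorm/encoder.py` — encoder contract, char-n-gram backend,
  embedding index, exact cosine retrieval
- `src/vaxnorm/ensemble.py` — fusion metrics, SM-Rule, corpus driver
- `src/vaxnorm/evaluation.py` — Acc@n, error taxonomy, reports
- `src/vaxnorm/fixtures.py` — deterministic synthetic data generator
- `src/vaxnorm/pipeline.py`, `src/vaxnorm/cli.py` — end-to-end driver and
  the thin command-line layer

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
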