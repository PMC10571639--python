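"""End-to-end driver: simulate → extract → index → normalize → evaluate.

Runs the full normalization study at fixture scale with two character
n-gram backends standing in as the model pool.  Fusion weights follow the
validation-proportional default: per-model Top-1 accuracy is measured on a
separate seeded validation corpus and the best models are weighted
proportionally.  Every artifact is written under an output directory and the
whole run is deterministic per seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import encoder, ensemble, evaluation, extraction, fixtures, ontology

DEFAULT_NGRAMS: tuple[tuple[int, int], ...] = ((3, 3), (2, 4))


@dataclass
class PipelineResult:
    out_dir: Path
    graph: ontology.ConceptGraph
    report: extraction.ExtractionReport
    weights: dict[str, float]
    #: (metric, sm_rule) → EvalReport
    evals: dict[tuple[str, bool], evaluation.EvalReport] = field(default_factory=dict)


def run_pipeline(
    seed: int,
    out_dir: str | Path,
    *,
    n_vaccine: int = 80,
    n_distractor: int = 20,
    n_mentions: int = 200,
    n_background: int = 300,
    noise: fixtures.NoiseConfig | None = None,
    ngram_ranges: tuple[tuple[int, int], ...] = DEFAULT_NGRAMS,
    metrics: tuple[str, ...] = ensemble.METRICS,
    k: int = 10,
) -> PipelineResult:
    """Run the whole study once; returns the evaluation reports per config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. synthetic study inputs
    graph = fixtures.make_ontology(n_vaccine, n_distractor, seed=seed)
    ontology.write_vocabulary(graph, out / "vocabulary.tsv")
    noise = noise or fixtures.NoiseConfig(seed=seed)
    entries, gold = fixtures.make_mentions(graph, n_mentions, noise)
    fixtures.write_mention_entries(entries, out / "mentions.tsv")
    gold.to_tsv(out / "gold.tsv")
    interventions = fixtures.make_interventions(entries, n_background, seed)
    fixtures.write_interventions(interventions, out / "interventions.csv")

    # 2. extraction pass over the interventions table
    records = extraction.read_interventions(out / "interventions.csv")
    corpus, report = extraction.build_corpus(records, graph)
    extraction.write_mentions(corpus, out / "extracted_mentions.tsv")
    report.to_json(out / "extraction_report.json")
    q1, q2 = extraction.emit_sql(graph)
    (out / "query1.sql").write_text(q1 + "\n")
    (out / "query2.sql").write_text(q2 + "\n")

    # 3. model pool: char n-gram backends over the vocabulary names
    names = [name for _, name in graph.iter_names()]
    backends = {b.name: b for b in (encoder.char_ngram_backend(names, r) for r in ngram_ranges)}
    indexes = {m: encoder.build_index(graph, b) for m, b in backends.items()}

    # 4. fusion weights from a held-out validation corpus
    val_noise = dataclasses.replace(noise, seed=seed + 10007)
    val_entries, val_gold = fixtures.make_mentions(graph, n_mentions, val_noise)
    acc1 = {}
    for model in sorted(backends):
        cfg = ensemble.EnsembleConfig({model: 1.0}, metric="score", k=k, sm_rule=False)
        preds = ensemble.normalize_corpus(
            [(e.mention_id, e.mention) for e in val_entries], graph, indexes, backends, cfg
        )
        acc1[model] = evaluation.topn_accuracy(preds, val_gold, 1)
    weights = ensemble.weights_from_validation(acc1)
    (out / "weights.json").write_text(json.dumps(weights, indent=2, sort_keys=True) + "\n")

    # 5. normalize and evaluate the study corpus under every configuration
    result = PipelineResult(out, graph, report, weights)
    mention_pairs = [(e.mention_id, e.mention) for e in entries]
    for metric in metrics:
        for sm in (False, True):
            cfg = ensemble.EnsembleConfig(weights, metric=metric, k=k, sm_rule=sm)
            preds = ensemble.normalize_corpus(mention_pairs, graph, indexes, backends, cfg)
            tag = f"{metric}{'_sm' if sm else ''}"
            ensemble.write_predictions_jsonl(preds, out / f"predictions_{tag}.jsonl")
            rep = evaluation.evaluate(preds, gold, graph, max_n=k)
            rep.to_json(out / f"eval_{tag}.json")
            (out / f"eval_{tag}.txt").write_text(rep.to_grid(f"ensemble+{metric}{'+sm-rule' if sm else ''}"))
            result.evals[(metric, sm)] = rep
    return result
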