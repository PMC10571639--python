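"""Weighted rule-based fusion of multiple rankers, plus the SM promotion rule.

Three fusion metrics combine per-model candidate lists into one ranking:

``score``
    weighted sum of raw cosine similarities (0 for concepts a model did not
    suggest in its top-K);
``scale``
    the same, after min-max rescaling each model's top-K scores to [0, 1]
    (a degenerate list where max == min contributes 1 for every present
    candidate);
``rank``
    Borda points ``K − rank + 1`` per model, weighted and summed.

The string-matching rule (SM-Rule) then promotes to rank 1 the concept whose
label or synonym occurs verbatim (case-folded) inside the mention, choosing
the longest such name.  Promotion reorders without rescoring, so it affects
top-n accuracy only through candidate order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._text import fold
from .encoder import Candidate, CandidateList, EmbeddingIndex, EncoderBackend, retrieve
from .ontology import ConceptGraph

METRICS = ("score", "scale", "rank")


@dataclass
class EnsembleConfig:
    """Fusion settings: metric, per-model weights, depth K, SM-Rule toggle."""

    weights: Mapping[str, float]
    metric: str = "scale"
    k: int = 10
    sm_rule: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class SmMatch:
    concept_id: str
    name: str


@dataclass
class RankedPrediction:
    """The fused, rule-adjusted final ranking for one mention."""

    mention: str
    candidates: list[Candidate]
    sm_promoted: SmMatch | None = None
    mention_id: str | None = None

    @property
    def top(self) -> Candidate:
        return self.candidates[0]


def fuse(lists: Mapping[str, CandidateList], config: EnsembleConfig) -> RankedPrediction:
    """Fuse per-model candidate lists into one ranking.

    All lists must refer to the same mention and every positively weighted
    model must be present.  Models are iterated in sorted-name order so the
    result is independent of the mapping's iteration order.
    """
    active = {m: w for m, w in config.weights.items() if w > 0}
    missing = sorted(set(active) - set(lists))
    if missing:
        raise ValueError(f"weighted models missing from lists: {missing}")
    mentions = {lists[m].mention for m in active}
    if len(mentions) != 1:
        raise ValueError(f"candidate lists refer to different mentions: {sorted(mentions)}")
    (mention,) = mentions

    fused: dict[str, float] = {}
    for model in sorted(active):
        weight = active[model]
        top = lists[model].candidates[: config.k]
        if not top:
            continue
        if config.metric == "score":
            contrib = [(c.concept_id, c.score) for c in top]
        elif config.metric == "scale":
            lo = min(c.score for c in top)
            hi = max(c.score for c in top)
            if hi == lo:
                contrib = [(c.concept_id, 1.0) for c in top]
            else:
                contrib = [(c.concept_id, (c.score - lo) / (hi - lo)) for c in top]
        else:  # rank → Borda points
            contrib = [(c.concept_id, float(config.k - c.rank + 1)) for c in top]
        for cid, s in contrib:
            fused[cid] = fused.get(cid, 0.0) + weight * s

    ordered = sorted(fused.items(), key=lambda t: (-t[1], t[0]))
    return RankedPrediction(
        mention=mention,
        candidates=[Candidate(cid, s, r) for r, (cid, s) in enumerate(ordered, 1)],
    )


def apply_sm_rule(graph: ConceptGraph, pred: RankedPrediction) -> RankedPrediction:
    """Promote a concept whose name occurs verbatim inside the mention.

    All labels and synonyms are matched case-folded as contiguous substrings
    of the case-folded mention.  The longest matched name wins (ties: the
    lexicographically smallest folded name, then the smallest concept id);
    its concept moves to rank 1 — inserted if absent — while the relative
    order of all other candidates is preserved.  With no match the prediction
    is returned unchanged.  Idempotent.
    """
    if len(graph) == 0:
        raise ValueError("graph must be non-empty")
    hay = fold(pred.mention)
    best: tuple[int, str, str, str] | None = None  # (-len, folded, cid, raw)
    for cid, raw in graph.iter_names():
        f = fold(raw)
        if f and f in hay:
            key = (-len(f), f, cid, raw)
            if best is None or key < best:
                best = key
    if best is None:
        return pred
    _, _, cid, raw = best
    existing = {c.concept_id: c for c in pred.candidates}
    promoted_score = existing[cid].score if cid in existing else 0.0
    rest = [c for c in pred.candidates if c.concept_id != cid]
    new = [Candidate(cid, promoted_score, 1)] + [
        Candidate(c.concept_id, c.score, r) for r, c in enumerate(rest, 2)
    ]
    return RankedPrediction(
        mention=pred.mention,
        candidates=new,
        sm_promoted=SmMatch(cid, raw),
        mention_id=pred.mention_id,
    )


def weights_from_validation(acc1_by_model: Mapping[str, float], top: int = 3) -> dict[str, float]:
    """Default fusion weights: proportional to validation Acc@1, best *top* models.

    Models outside the top *top* by Acc@1 get weight 0; if all retained
    accuracies are 0 the retained models are weighted equally.
    """
    if not acc1_by_model:
        raise ValueError("acc1_by_model must be non-empty")
    ranked = sorted(acc1_by_model.items(), key=lambda t: (-t[1], t[0]))[:top]
    total = sum(a for _, a in ranked)
    if total == 0:
        return {m: 1.0 / len(ranked) for m, _ in ranked}
    return {m: a / total for m, a in ranked}


def write_predictions_jsonl(predictions: Sequence[RankedPrediction], path) -> None:
    """Write predictions as JSONL: one object per mention, stable field order."""
    import json
    from pathlib import Path

    lines = []
    for p in predictions:
        obj = {
            "mention_id": p.mention_id,
            "mention": p.mention,
            "candidates": [
                {"concept_id": c.concept_id, "score": c.score, "rank": c.rank}
                for c in p.candidates
            ],
            "sm_promoted": (
                {"concept_id": p.sm_promoted.concept_id, "name": p.sm_promoted.name}
                if p.sm_promoted
                else None
            ),
        }
        lines.append(json.dumps(obj))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_predictions_jsonl(path) -> list[RankedPrediction]:
    import json
    from pathlib import Path

    preds = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        preds.append(
            RankedPrediction(
                mention=obj["mention"],
                candidates=[
                    Candidate(c["concept_id"], c["score"], c["rank"])
                    for c in obj["candidates"]
                ],
                sm_promoted=(
                    SmMatch(obj["sm_promoted"]["concept_id"], obj["sm_promoted"]["name"])
                    if obj.get("sm_promoted")
                    else None
                ),
                mention_id=obj.get("mention_id"),
            )
        )
    return preds


def normalize_corpus(
    mentions: Sequence[str] | Sequence[tuple[str, str]],
    graph: ConceptGraph,
    indexes: Mapping[str, EmbeddingIndex],
    backends: Mapping[str, EncoderBackend],
    config: EnsembleConfig,
) -> list[RankedPrediction]:
    """Pipeline driver: retrieve per model → fuse → optional SM-Rule.

    *mentions* is a list of strings or of ``(mention_id, text)`` pairs; one
    :class:`RankedPrediction` is returned per mention, in input order.
    """
    if set(indexes) != set(backends):
        raise ValueError("indexes and backends must cover the same model names")
    out = []
    for item in mentions:
        mid, text = item if isinstance(item, tuple) else (None, item)
        lists = {
            model: retrieve(text, indexes[model], backends[model], config.k)
            for model in sorted(indexes)
        }
        pred = fuse(lists, config)
        pred.mention_id = mid
        if config.sm_rule:
            pred = apply_sm_rule(graph, pred)
        out.append(pred)
    return out
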