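"""Top-n accuracy and ontology-aware error classification.

Predictions are scored against a possibly multi-valued gold standard: a
mention counts as correct at depth *n* when any of its gold concepts appears
among the top *n* candidates.  Every mention wrong at rank 1 receives one
:class:`ErrorRecord` whose type comes from a fixed priority of rules —
out-of-vocabulary gold, multi-concept mentions, disambiguation (gold present
lower in the list), hierarchy relations from the concept graph, linguistic
heuristics (abbreviation / spelling / stemming / dose-noise), and finally the
residual ``semantic`` type for deep or unrelated confusions.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import pandas as pd

from ._text import fold, tokens
from .ensemble import RankedPrediction
from .ontology import ConceptGraph, UnknownConceptError, classify_relation

#: Sentinel gold id marking a mention whose true concept is absent from the
#: vocabulary (out-of-vocabulary by construction).
OOV_ID = "OOV"

ERROR_TYPES = (
    "ner_multi_concept",
    "ner_noise",
    "abbreviation",
    "disambiguation",
    "hierarchy_parent_child",
    "hierarchy_sibling",
    "hierarchy_ancestor_descendant",
    "semantic",
    "stemming",
    "spelling",
    "oov",
)

_RELATION_PRIORITY = {"exact": 0, "parent_child": 1, "ancestor_descendant": 2, "sibling": 3, "semantic": 4, "oov": 5}

_DOSE_RE = re.compile(
    r"(\b\d+(\.\d+)?\s*(mg|ml|mcg|µg|ug|iu|units?|doses?)\b)|(\blot\b)", re.IGNORECASE
)


@dataclass
class GoldStandard:
    """mention_id → non-empty set of gold concept ids (OOV sentinel allowed)."""

    mapping: dict[str, frozenset[str]]
    mentions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, ids in self.mapping.items():
            if not ids:
                raise ValueError(f"gold set for {mid!r} is empty")

    def validate(self, graph: ConceptGraph) -> None:
        """Check that every non-sentinel gold id resolves in *graph*."""
        for mid, ids in self.mapping.items():
            for g in ids:
                if g != OOV_ID and g not in graph:
                    raise UnknownConceptError(f"gold id {g!r} for {mid!r} not in graph")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoldStandard":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        need = {"mention_id", "mention", "gold_ids"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
        mapping = {
            r.mention_id: frozenset(g for g in r.gold_ids.split("|") if g)
            for r in df.itertuples(index=False)
        }
        mentions = {r.mention_id: r.mention for r in df.itertuples(index=False)}
        return cls(mapping, mentions)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "mention_id": mid,
                "mention": self.mentions.get(mid, ""),
                "gold_ids": "|".join(sorted(ids)),
            }
            for mid, ids in self.mapping.items()
        ]
        pd.DataFrame(rows, columns=["mention_id", "mention", "gold_ids"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ErrorRecord:
    mention_id: str
    gold_ids: frozenset[str]
    predicted_id: str
    relation: str
    error_type: str
    rank_of_gold: int | None


@dataclass
class EvalReport:
    """Acc@1..N vector plus per-mention error records for rank-1 misses."""

    n_mentions: int
    acc: list[float]
    error_histogram: dict[str, int]
    records: list[ErrorRecord]

    def to_dict(self) -> dict:
        return {
            "n_mentions": self.n_mentions,
            "acc": self.acc,
            "error_histogram": dict(sorted(self.error_histogram.items())),
            "errors": [
                {
                    "mention_id": r.mention_id,
                    "gold_ids": sorted(r.gold_ids),
                    "predicted_id": r.predicted_id,
                    "relation": r.relation,
                    "error_type": r.error_type,
                    "rank_of_gold": r.rank_of_gold,
                }
                for r in self.records
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_grid(self, model: str = "model") -> str:
        """Plain-text Acc@1..N grid (accuracies printed as percentages)."""
        header = "Model\t" + "\t".join(f"Acc@{n}" for n in range(1, len(self.acc) + 1))
        row = model + "\t" + "\t".join(f"{100 * a:.1f}" for a in self.acc)
        return header + "\n" + row + "\n"


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def topn_accuracy(
    predictions: Sequence[RankedPrediction], gold: GoldStandard, n: int
) -> float:
    """Fraction of mentions with a gold id among the top min(n, len) candidates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not predictions:
        return 0.0
    hits = 0
    for pred in predictions:
        if pred.mention_id not in gold.mapping:
            raise ValueError(f"mention {pred.mention_id!r} absent from gold standard")
        gold_ids = gold.mapping[pred.mention_id]
        top = pred.candidates[: min(n, len(pred.candidates))]
        hits += any(c.concept_id in gold_ids for c in top)
    return hits / len(predictions)


def _rank_of_gold(pred: RankedPrediction, gold_ids: frozenset[str]) -> int | None:
    for c in pred.candidates:
        if c.concept_id in gold_ids:
            return c.rank
    return None


# ---------------------------------------------------------------------------
# linguistic heuristics (all overridable via the `hooks` argument)
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def _initials(label: str) -> str:
    return "".join(t[0] for t in tokens(label)).upper()


def _is_abbreviation(mention: str, gold_labels: Sequence[str]) -> bool:
    caps = [t for t in tokens(mention) if t.isupper() and 2 <= len(t) <= 6]
    targets = {_initials(lbl) for lbl in gold_labels if len(tokens(lbl)) >= 2}
    return any(t in targets for t in caps)


def _is_spelling(mention: str, gold_labels: Sequence[str]) -> bool:
    m_toks = {t.lower() for t in tokens(mention) if len(t) >= 3}
    g_toks = {t.lower() for lbl in gold_labels for t in tokens(lbl) if len(t) >= 3}
    for mt in m_toks:
        for gt in g_toks:
            if mt != gt and 1 <= _edit_distance(mt, gt) <= 2:
                return True
    return False


def _is_stemming(mention: str, gold_labels: Sequence[str]) -> bool:
    m_toks = {t.lower() for t in tokens(mention) if len(t) >= 4}
    g_toks = {t.lower() for lbl in gold_labels for t in tokens(lbl) if len(t) >= 4}
    for mt in m_toks:
        for gt in g_toks:
            if mt != gt and mt[:4] == gt[:4]:
                return True
    return False


def _is_dose_noise(mention: str) -> bool:
    return bool(_DOSE_RE.search(mention))


# ---------------------------------------------------------------------------
# error classification
# ---------------------------------------------------------------------------

def classify_error(
    graph: ConceptGraph,
    gold_ids: Iterable[str],
    pred: RankedPrediction,
    *,
    k: int = 10,
    heuristics: bool = True,
    hooks: Mapping[str, Callable[[str, Sequence[str]], bool]] | None = None,
) -> ErrorRecord:
    """Assign one error type to a mention that is wrong at rank 1.

    The relation between the top prediction and the *nearest* gold concept
    (best relation under exact > parent_child > ancestor_descendant >
    sibling > semantic) feeds the hierarchy branch.  ``hooks`` may replace
    any linguistic heuristic by name (``abbreviation``, ``spelling``,
    ``stemming``, ``ner_noise``); each hook receives ``(mention, gold
    labels)`` and returns a bool.
    """
    gold_ids = frozenset(gold_ids)
    if not gold_ids:
        raise ValueError("gold_ids must be non-empty")
    if not pred.candidates:
        raise ValueError(f"prediction for {pred.mention!r} has no candidates")
    in_graph = sorted(g for g in gold_ids if g != OOV_ID and g in graph)
    missing = sorted(g for g in gold_ids if g != OOV_ID and g not in graph)
    if missing:
        raise UnknownConceptError(f"gold ids not in graph: {missing}")

    top_id = pred.top.concept_id
    rank_of_gold = _rank_of_gold(pred, gold_ids)
    if rank_of_gold == 1:
        raise ValueError("prediction is correct at rank 1; no error to classify")

    if not in_graph:
        return ErrorRecord(pred.mention_id or "", gold_ids, top_id, "oov", "oov", rank_of_gold)

    relations = {g: classify_relation(graph, g, top_id) for g in in_graph}
    nearest = min(in_graph, key=lambda g: (_RELATION_PRIORITY[relations[g]], g))
    relation = relations[nearest]
    gold_labels = [graph[g].label for g in in_graph]

    checks = {
        "abbreviation": _is_abbreviation,
        "spelling": _is_spelling,
        "stemming": _is_stemming,
        "ner_noise": lambda m, _lbls: _is_dose_noise(m),
    }
    if hooks:
        checks.update(hooks)

    def lingo(name: str) -> bool:
        return heuristics and checks[name](pred.mention, gold_labels)

    if len(gold_ids) >= 2:
        etype = "ner_multi_concept"
    elif rank_of_gold is not None and 2 <= rank_of_gold <= k:
        etype = "disambiguation"
    elif relation in ("parent_child", "ancestor_descendant", "sibling"):
        etype = f"hierarchy_{relation}"
    elif lingo("abbreviation"):
        etype = "abbreviation"
    elif lingo("spelling"):
        etype = "spelling"
    elif lingo("stemming"):
        etype = "stemming"
    elif lingo("ner_noise"):
        etype = "ner_noise"
    else:
        etype = "semantic"
    return ErrorRecord(pred.mention_id or "", gold_ids, top_id, relation, etype, rank_of_gold)


def evaluate(
    predictions: Sequence[RankedPrediction],
    gold: GoldStandard,
    graph: ConceptGraph,
    max_n: int = 10,
    *,
    heuristics: bool = True,
    hooks: Mapping[str, Callable[[str, Sequence[str]], bool]] | None = None,
) -> EvalReport:
    """Score predictions with Acc@1..max_n and classify every rank-1 miss."""
    acc = [topn_accuracy(predictions, gold, n) for n in range(1, max_n + 1)]
    assert all(a <= b + 1e-12 for a, b in zip(acc, acc[1:])), "Acc@n must be monotone"
    records = []
    for pred in predictions:
        gold_ids = gold.mapping[pred.mention_id]
        if pred.candidates and pred.top.concept_id in gold_ids:
            continue
        records.append(
            classify_error(graph, gold_ids, pred, k=max_n, heuristics=heuristics, hooks=hooks)
        )
    histogram: dict[str, int] = {}
    for r in records:
        histogram[r.error_type] = histogram.get(r.error_type, 0) + 1
    return EvalReport(len(predictions), acc, histogram, records)
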