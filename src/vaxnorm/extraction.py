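"""Mining vaccine mentions from a clinical-trial interventions table.

Trial registries do not flag interventions as vaccines, so candidate mentions
are pulled from the interventions table with two string-matching passes over
rows typed ``Biological``: a vocabulary pass (any concept name occurs as a
substring of the intervention name, mirroring SQL ``position(lower(x) IN
lower(name)) > 0``) and a keyword pass (``lower(name) LIKE '%vaccine%'``).
The two result sets are unioned, duplicate names are collapsed, and the
stage-by-stage counts are kept in a PRISMA-style :class:`ExtractionReport`.

When one intervention matches several vocabulary names, a TF-IDF string
similarity matcher over character 3-grams resolves the single best name.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from ._text import fold
from .ontology import ConceptGraph

BIOLOGICAL = "Biological"  # exact, case-sensitive per the registry's SQL literal

CSV_COLUMNS = ("id", "nct_id", "intervention_type", "name")


@dataclass(frozen=True)
class InterventionRecord:
    """One row of the interventions table."""

    id: int
    nct_id: str
    intervention_type: str
    name: str


@dataclass
class ExtractionReport:
    """PRISMA-style stage counts for the extraction pipeline."""

    n_total: int
    n_biological: int
    n_query1: int
    n_query2: int
    n_union: int
    n_unique: int

    def __post_init__(self) -> None:
        ok = (
            self.n_unique <= self.n_union <= self.n_query1 + self.n_query2
            and self.n_query1 <= self.n_biological <= self.n_total
            and self.n_query2 <= self.n_biological
        )
        if not ok:
            raise ValueError(f"inconsistent extraction counts: {asdict(self)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


class MentionRow(NamedTuple):
    mention: str
    nct_id: str


def read_interventions(path: str | Path) -> list[InterventionRecord]:
    """Read an interventions CSV (columns id, nct_id, intervention_type, name)."""
    df = pd.read_csv(path, dtype={"id": int, "nct_id": str, "intervention_type": str, "name": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        InterventionRecord(int(r.id), r.nct_id, r.intervention_type, r.name)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# the two selection queries
# ---------------------------------------------------------------------------

def select_by_vocabulary(
    records: Iterable[InterventionRecord], graph: ConceptGraph
) -> list[tuple[InterventionRecord, list[str]]]:
    """Rows typed Biological whose name contains a concept name as a substring.

    All matching vocabulary names (labels and synonyms, case-folded contiguous
    substring match) are attached to each returned record.
    """
    if len(graph) == 0:
        raise ValueError("vocabulary graph is empty")
    names = [(fold(name), name) for _, name in graph.iter_names()]
    out = []
    for rec in records:
        if rec.intervention_type != BIOLOGICAL:
            continue
        hay = fold(rec.name)
        matched = [raw for folded, raw in names if folded and folded in hay]
        if matched:
            out.append((rec, matched))
    return out


def select_by_keyword(
    records: Iterable[InterventionRecord], keywords: Sequence[str] = ("vaccine",)
) -> list[InterventionRecord]:
    """Rows typed Biological whose name contains any keyword as a substring."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    folded = [fold(k) for k in keywords]
    return [
        rec
        for rec in records
        if rec.intervention_type == BIOLOGICAL
        and any(k in fold(rec.name) for k in folded)
    ]


# ---------------------------------------------------------------------------
# TF-IDF unique-term resolution
# ---------------------------------------------------------------------------

class TfidfStringMatcher:
    """Cosine similarity between TF-IDF vectors of character n-grams.

    Fitted once on a corpus (typically the vocabulary names); symmetric, and
    1.0 for identical strings with at least one in-vocabulary n-gram.
    """

    def __init__(self, ngram_range: tuple[int, int] = (3, 3)):
        self._vec = TfidfVectorizer(analyzer="char", ngram_range=ngram_range, preprocessor=fold)
        self._fitted = False

    def fit(self, corpus: Sequence[str]) -> "TfidfStringMatcher":
        if not corpus:
            raise ValueError("corpus must be non-empty")
        self._vec.fit(corpus)
        self._fitted = True
        return self

    def similarity(self, a: str, b: str) -> float:
        if not self._fitted:
            raise RuntimeError("matcher not fitted; call fit() first")
        m = self._vec.transform([a, b])  # rows are L2-normalized
        return float((m[0] @ m[1].T).toarray()[0, 0])


def tfidf_similarity(a: str, b: str, index: TfidfStringMatcher) -> float:
    """Cosine TF-IDF similarity of *a* and *b* under a fitted matcher."""
    return index.similarity(a, b)


def resolve_unique_concept(
    mention: str, matched_names: Sequence[str], index: TfidfStringMatcher
) -> str:
    """Pick the single vocabulary name most similar to *mention*.

    Ties on the cosine score are broken by longer name, then lexicographic
    order.
    """
    if not matched_names:
        raise ValueError("matched_names must be non-empty")
    scored = [(index.similarity(mention, n), len(n), n) for n in matched_names]
    return min(scored, key=lambda t: (-t[0], -t[1], t[2]))[2]


# ---------------------------------------------------------------------------
# combine + dedupe
# ---------------------------------------------------------------------------

def build_corpus(
    records: Sequence[InterventionRecord],
    graph: ConceptGraph,
    keywords: Sequence[str] = ("vaccine",),
) -> tuple[list[MentionRow], ExtractionReport]:
    """Union the two queries and dedupe mention strings.

    The dedupe key is the case-folded, whitespace-collapsed name; within a
    duplicate group the lexicographically smallest raw form and nct_id are
    kept, and the output is sorted by the dedupe key, so the corpus does not
    depend on input row order.
    """
    q1 = select_by_vocabulary(records, graph)
    q2 = select_by_keyword(records, keywords)
    union: dict[int, InterventionRecord] = {rec.id: rec for rec, _ in q1}
    union.update((rec.id, rec) for rec in q2)
    groups: dict[str, tuple[str, str]] = {}
    for rec in union.values():
        key = fold(rec.name)
        cand = (rec.name, rec.nct_id)
        if key not in groups or cand < groups[key]:
            groups[key] = cand
    mentions = [MentionRow(m, n) for _, (m, n) in sorted(groups.items())]
    report = ExtractionReport(
        n_total=len(records),
        n_biological=sum(r.intervention_type == BIOLOGICAL for r in records),
        n_query1=len(q1),
        n_query2=len(q2),
        n_union=len(union),
        n_unique=len(mentions),
    )
    return mentions, report


def write_mentions(rows: Sequence[MentionRow], path: str | Path) -> None:
    """Write a mentions TSV: mention_id, nct_id, mention."""
    df = pd.DataFrame(
        {
            "mention_id": [f"M{i:04d}" for i in range(1, len(rows) + 1)],
            "nct_id": [r.nct_id for r in rows],
            "mention": [r.mention for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SQL rendering (for users with a live registry database)
# ---------------------------------------------------------------------------

_Q1_TEMPLATE = (
    "SELECT DISTINCT id, nct_id, name FROM ctgov.interventions\n"
    "WHERE intervention_type='Biological'\n"
    "  AND ({clauses});"
)
_Q2_TEMPLATE = (
    "SELECT DISTINCT id, nct_id, name FROM ctgov.interventions\n"
    "WHERE intervention_type='Biological'\n"
    "  AND ({clauses});"
)


def _sql_quote(text: str) -> str:
    return text.replace("'", "''")


def emit_sql(graph: ConceptGraph, keywords: Sequence[str] = ("vaccine",)) -> tuple[str, str]:
    """Render the vocabulary and keyword selection queries as SQL text.

    Query 1 gets one ``position(lower('<name>') IN lower(name)) > 0`` clause
    per vocabulary name (labels and synonyms, matching the in-memory
    semantics); query 2 gets one ``lower(name) LIKE '%<kw>%'`` clause per
    keyword.  Quotes are escaped; an empty vocabulary yields a query with a
    constant-false clause and a warning.
    """
    name_clauses = [
        f"position(lower('{_sql_quote(name)}') IN lower(name)) > 0"
        for _, name in graph.iter_names()
    ]
    if not name_clauses:
        warnings.warn("empty vocabulary: query 1 emitted with no label clauses")
        name_clauses = ["false"]
    kw_clauses = [f"lower(name) LIKE '%{_sql_quote(fold(k))}%'" for k in keywords]
    if not kw_clauses:
        raise ValueError("keywords must be non-empty")
    q1 = _Q1_TEMPLATE.format(clauses="\n       OR ".join(name_clauses))
    q2 = _Q2_TEMPLATE.format(clauses="\n       OR ".join(kw_clauses))
    return q1, q2
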