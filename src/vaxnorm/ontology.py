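"""Concept vocabulary: loading, vaccine-subtree filtering, and hierarchy queries.

The normalization target space is a DAG of concepts (emulating the Vaccine
Ontology): each concept has a CURIE-style id, a preferred label, optional
synonyms, and zero or more ``is_a`` parents.  Two read formats are supported —
a minimal OBO 1.4 subset (``[Term]`` stanzas with ``id``/``name``/``synonym``/
``is_a``) and a flat TSV dialect — plus a TSV writer that round-trips.

The module also classifies the ontological relation between a gold and a
predicted concept, which drives the hierarchy branch of the error taxonomy:
a direct parent edge is ``parent_child``, a shortest directed path of exactly
two edges is ``ancestor_descendant``, a shared parent without any ancestor
path is ``sibling``, and everything else in-vocabulary (paths spanning more
than two levels, or unrelated concepts) is ``semantic``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from ._text import fold

RELATIONS = ("exact", "parent_child", "ancestor_descendant", "sibling", "semantic", "oov")

TSV_COLUMNS = ("id", "label", "synonyms", "parents", "is_vaccine")


class VocabularyError(ValueError):
    """Base class for vocabulary loading/structure failures."""


class VocabularyParseError(VocabularyError):
    """The source file could not be parsed; the message names the record/line."""


class CycleError(VocabularyError):
    """The parent relation contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__(f"parent links form a cycle: {' -> '.join(self.cycle)}")


class UnknownConceptError(KeyError):
    """A referenced concept id is absent from the graph."""


@dataclass(frozen=True)
class Concept:
    """One vocabulary entry: id, preferred label, synonyms and is_a parents."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    is_vaccine: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise VocabularyError("concept id must be non-empty")
        if not self.label:
            raise VocabularyError(f"concept {self.id!r} has an empty label")
        # synonyms: preserve order, drop duplicates and copies of the label
        seen: set[str] = {self.label}
        cleaned = []
        for s in self.synonyms:
            if s and s not in seen:
                cleaned.append(s)
                seen.add(s)
        object.__setattr__(self, "synonyms", tuple(cleaned))
        object.__setattr__(self, "parent_ids", tuple(dict.fromkeys(self.parent_ids)))

    @property
    def names(self) -> tuple[str, ...]:
        return (self.label, *self.synonyms)


class ConceptGraph(Mapping[str, Concept]):
    """An acyclic concept hierarchy with an all-names lookup index.

    Parent edges are stored child → parent in a :class:`networkx.DiGraph`,
    so "ancestors" of a concept are reachable by following edges forward.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise VocabularyError(f"duplicate concept id {c.id!r}")
            self._concepts[c.id] = c
        for c in self._concepts.values():
            for p in c.parent_ids:
                if p not in self._concepts:
                    raise VocabularyError(
                        f"concept {c.id!r} names unknown parent {p!r}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        g.add_edges_from(
            (c.id, p) for c in self._concepts.values() for p in c.parent_ids
        )
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(nx.find_cycle(g)[0])
        self._dag = g

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, cid: str) -> Concept:
        try:
            return self._concepts[cid]
        except KeyError:
            raise UnknownConceptError(cid) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._concepts)

    def __len__(self) -> int:
        return len(self._concepts)

    # -- structure --------------------------------------------------------
    @property
    def concepts(self) -> dict[str, Concept]:
        return dict(self._concepts)

    @property
    def roots(self) -> set[str]:
        return {cid for cid, c in self._concepts.items() if not c.parent_ids}

    def ancestors(self, cid: str) -> set[str]:
        """All concepts reachable from *cid* via parent links (excludes *cid*)."""
        if cid not in self._concepts:
            raise UnknownConceptError(cid)
        return nx.descendants(self._dag, cid)

    def descendants(self, cid: str) -> set[str]:
        """All concepts whose ancestor closure contains *cid* (excludes *cid*)."""
        if cid not in self._concepts:
            raise UnknownConceptError(cid)
        return nx.ancestors(self._dag, cid)

    def path_length(self, lower: str, upper: str) -> int | None:
        """Shortest directed is_a path lower → upper, or None if no path."""
        try:
            return nx.shortest_path_length(self._dag, lower, upper)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None

    # -- names ------------------------------------------------------------
    def iter_names(self) -> Iterator[tuple[str, str]]:
        """Yield (concept_id, name) for every label and synonym, in id order."""
        for cid in sorted(self._concepts):
            for name in self._concepts[cid].names:
                yield cid, name

    def all_names(self) -> dict[str, list[tuple[str, str]]]:
        """Case-folded name → list of (concept_id, raw name); total over concepts."""
        index: dict[str, list[tuple[str, str]]] = {}
        for cid, name in self.iter_names():
            index.setdefault(fold(name), []).append((cid, name))
        return index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptGraph):
            return NotImplemented
        return self._concepts == other._concepts


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def load_vocabulary(source: str | Path, format: str | None = None) -> ConceptGraph:
    """Load a concept vocabulary from an OBO flat file or the TSV dialect.

    ``format`` is ``"obo"`` or ``"tsv"``; when omitted it is inferred from
    the file suffix.  Raises :class:`VocabularyParseError` on malformed input
    (naming the offending record) and :class:`CycleError` on cyclic is_a links.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("obo" if path.suffix.lower() == ".obo" else "tsv")
    if fmt == "obo":
        return _load_obo(path)
    if fmt == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown vocabulary format {fmt!r}")


def _load_obo(path: Path) -> ConceptGraph:
    try:
        g = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises ValueError with line context
        raise VocabularyParseError(f"{path}: malformed OBO file: {exc}") from exc
    if len(g) == 0:
        raise VocabularyParseError(f"{path}: no [Term] stanzas found")
    concepts = []
    for cid, data in g.nodes(data=True):
        name = data.get("name")
        if not name:
            raise VocabularyParseError(f"{path}: term {cid!r} has no name tag")
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if not m:
                raise VocabularyParseError(
                    f"{path}: term {cid!r} has malformed synonym {raw!r}"
                )
            synonyms.append(m.group(1))
        # obonet stores is_a links as child -> parent edges keyed by relation
        parents = sorted(v for _, v, k in g.out_edges(cid, keys=True) if k == "is_a")
        concepts.append(Concept(cid, name, tuple(synonyms), tuple(parents)))
    return ConceptGraph(concepts)


def _load_tsv(path: Path) -> ConceptGraph:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise VocabularyParseError(f"{path}: malformed TSV: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VocabularyParseError(f"{path}: missing columns {missing}")
    concepts = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            concepts.append(
                Concept(
                    id=row.id,
                    label=row.label,
                    synonyms=tuple(s for s in row.synonyms.split("|") if s),
                    parent_ids=tuple(p for p in row.parents.split("|") if p),
                    is_vaccine=row.is_vaccine in ("1", "true", "True"),
                )
            )
        except VocabularyError as exc:
            raise VocabularyParseError(f"{path}: line {i}: {exc}") from exc
    if not concepts:
        raise VocabularyParseError(f"{path}: no concept rows")
    return ConceptGraph(concepts)


def write_vocabulary(graph: ConceptGraph, path: str | Path) -> None:
    """Write *graph* in the TSV dialect (id-sorted; round-trips via load)."""
    rows = [
        {
            "id": c.id,
            "label": c.label,
            "synonyms": "|".join(c.synonyms),
            "parents": "|".join(c.parent_ids),
            "is_vaccine": int(c.is_vaccine),
        }
        for c in (graph[cid] for cid in sorted(graph))
    ]
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# vaccine filter
# ---------------------------------------------------------------------------

def filter_vaccine_terms(
    graph: ConceptGraph,
    subtree_roots: Sequence[str] | None = None,
    predicate: Callable[[Concept], bool] | None = None,
) -> ConceptGraph:
    """Restrict the vocabulary to vaccine terms.

    Exactly one rule must be given: ``subtree_roots`` keeps the closure of
    the named subtrees (the roots plus everything below them), while
    ``predicate`` keeps concepts for which it returns True.  Parent links are
    restricted to retained concepts and ``is_vaccine`` is set on all of them.
    The operation is idempotent for a fixed rule.
    """
    if (subtree_roots is None) == (predicate is None):
        raise ValueError("give exactly one of subtree_roots or predicate")
    if subtree_roots is not None:
        keep: set[str] = set()
        for r in subtree_roots:
            if r not in graph:
                raise UnknownConceptError(r)
            keep.add(r)
            keep |= graph.descendants(r)
    else:
        assert predicate is not None
        keep = {cid for cid in graph if predicate(graph[cid])}
    new = [
        replace(
            graph[cid],
            parent_ids=tuple(p for p in graph[cid].parent_ids if p in keep),
            is_vaccine=True,
        )
        for cid in sorted(keep)
    ]
    return ConceptGraph(new)


# ---------------------------------------------------------------------------
# relation classification
# ---------------------------------------------------------------------------

def classify_relation(graph: ConceptGraph, gold_id: str, pred_id: str) -> str:
    """Ontological relation between a gold and a predicted concept.

    Returns one of :data:`RELATIONS`.  ``gold_id`` must be in the graph;
    ``pred_id`` may be absent (→ ``"oov"``).  Path lengths use the shortest
    directed is_a path in either direction.
    """
    if gold_id not in graph:
        raise UnknownConceptError(gold_id)
    if pred_id not in graph:
        return "oov"
    if gold_id == pred_id:
        return "exact"
    d_up = graph.path_length(gold_id, pred_id)
    d_down = graph.path_length(pred_id, gold_id)
    dists = [d for d in (d_up, d_down) if d is not None]
    if dists:
        d = min(dists)
        if d == 1:
            return "parent_child"
        if d == 2:
            return "ancestor_descendant"
        return "semantic"
    if set(graph[gold_id].parent_ids) & set(graph[pred_id].parent_ids):
        return "sibling"
    return "semantic"
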