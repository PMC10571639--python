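"""Pluggable text encoders and exact cosine retrieval over concept names.

A backend maps a list of strings to a matrix of unit-L2-norm row vectors.
Any externally trained sentence encoder (e.g. a fine-tuned domain BERT) can
be wrapped to satisfy the contract; the shipped backend is a deterministic
TF-IDF character n-gram vectorizer fitted on the vocabulary names, which
needs no model weights and makes every retrieval result reproducible.

An :class:`EmbeddingIndex` holds one vector per (concept, name) pair — the
label and every synonym — and retrieval max-pools over a concept's name
entries, so adding a synonym can never lower a concept's score.  Retrieval
is an exact brute-force cosine scan; no approximate index is used.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from ._text import fold
from .ontology import ConceptGraph


class BackendMismatchError(ValueError):
    """The index was built with a different backend than the one supplied."""


@runtime_checkable
class EncoderBackend(Protocol):
    """Deterministic text → unit-vector encoder."""

    name: str
    dimension: int

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # (n, dimension)
        ...


class CharNgramBackend:
    """TF-IDF character n-gram encoder fitted on the vocabulary names.

    Strings are case-folded (with ®/™ stripped and whitespace collapsed)
    before vectorization.  Rows are L2-normalized by the vectorizer; a string
    with no in-vocabulary n-gram encodes to the zero vector.
    """

    def __init__(self, vocabulary_names: Sequence[str], ngram_range: tuple[int, int] = (3, 3)):
        if not vocabulary_names:
            raise ValueError("vocabulary_names must be non-empty")
        self.ngram_range = (int(ngram_range[0]), int(ngram_range[1]))
        self._vec = TfidfVectorizer(
            analyzer="char", ngram_range=self.ngram_range, preprocessor=fold
        )
        self._vec.fit(vocabulary_names)
        self.dimension = len(self._vec.get_feature_names_out())
        self.name = f"char-ngram-{self.ngram_range[0]}-{self.ngram_range[1]}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return self._vec.transform(texts).toarray()


def char_ngram_backend(
    vocabulary_names: Sequence[str], ngram_range: tuple[int, int] = (3, 3)
) -> CharNgramBackend:
    """Build the fallback character n-gram backend from vocabulary names."""
    return CharNgramBackend(vocabulary_names, ngram_range)


@dataclass(frozen=True)
class Candidate:
    concept_id: str
    score: float
    rank: int  # 1-based


@dataclass
class CandidateList:
    """One backend's ranked concepts for one mention."""

    mention: str
    candidates: list[Candidate]
    backend_name: str


@dataclass
class EmbeddingIndex:
    """One unit vector per (concept, name) entry, tied to one backend."""

    concept_ids: list[str]
    names: list[str]
    matrix: np.ndarray  # (n_entries, dimension)
    backend_name: str


def build_index(graph: ConceptGraph, backend: EncoderBackend) -> EmbeddingIndex:
    """Encode every concept label and synonym into an index."""
    if len(graph) == 0:
        raise ValueError("graph must be non-empty")
    entries = sorted(graph.iter_names())  # (concept_id, name), deterministic order
    cids = [c for c, _ in entries]
    names = [n for _, n in entries]
    matrix = backend.encode(names)
    if matrix.shape != (len(names), backend.dimension):
        raise RuntimeError(
            f"backend {backend.name} returned shape {matrix.shape}, "
            f"expected {(len(names), backend.dimension)}"
        )
    return EmbeddingIndex(cids, names, matrix, backend.name)


def retrieve(
    mention: str, index: EmbeddingIndex, backend: EncoderBackend, k: int = 10
) -> CandidateList:
    """Top-*k* concepts for *mention* by exact cosine scan over all entries.

    A concept's score is the maximum cosine over its name entries; ties are
    broken by concept id ascending.  Scores are quantized to 12 decimals
    before ranking so that mathematically equal entries stay tied regardless
    of the BLAS accumulation order, keeping the id tie-break deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if backend.name != index.backend_name:
        raise BackendMismatchError(
            f"index built with {index.backend_name!r}, got backend {backend.name!r}"
        )
    vec = backend.encode([mention])[0]
    sims = index.matrix @ vec
    best: dict[str, float] = {}
    for cid, s in zip(index.concept_ids, sims):
        s = round(float(s), 12)
        if cid not in best or s > best[cid]:
            best[cid] = s
    ordered = sorted(best.items(), key=lambda t: (-t[1], t[0]))[:k]
    return CandidateList(
        mention=mention,
        candidates=[Candidate(cid, s, r) for r, (cid, s) in enumerate(ordered, 1)],
        backend_name=backend.name,
    )


# ---------------------------------------------------------------------------
# persistence (entries TSV + matrix + manifest)
# ---------------------------------------------------------------------------

def save_index(index: EmbeddingIndex, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"concept_id": index.concept_ids, "name": index.names}).to_csv(
        d / "entries.tsv", sep="\t", index=False
    )
    np.save(d / "matrix.npy", index.matrix)
    manifest = {
        "backend_name": index.backend_name,
        "dimension": int(index.matrix.shape[1]),
        "n_entries": len(index.names),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_index(directory: str | Path) -> tuple[EmbeddingIndex, CharNgramBackend]:
    """Load a persisted index; rebuilds the char n-gram backend from entries.

    The backend was fitted on exactly the entry names, so refitting on them
    reproduces the identical vector space.  Only char-ngram backends can be
    reconstructed; other backends must be re-supplied by the caller.
    """
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    df = pd.read_csv(d / "entries.tsv", sep="\t", dtype=str, keep_default_na=False)
    matrix = np.load(d / "matrix.npy")
    index = EmbeddingIndex(
        list(df["concept_id"]), list(df["name"]), matrix, manifest["backend_name"]
    )
    bname = manifest["backend_name"]
    if not bname.startswith("char-ngram-"):
        raise BackendMismatchError(
            f"cannot reconstruct non-char-ngram backend {bname!r}; supply it explicitly"
        )
    lo, hi = (int(x) for x in bname.split("-")[-2:])
    backend = CharNgramBackend(index.names, (lo, hi))
    return index, backend
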