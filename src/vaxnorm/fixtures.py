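"""Deterministic synthetic data: ontology, noisy mentions, interventions table.

This module is synthetic by design: it emulates the *structure* of the real
inputs — a vaccine ontology with products and distractor (non-vaccine)
branches, free-text intervention names with product parentheticals, placebo
suffixes, abbreviations, dose tokens and misspellings, and a registry-style
interventions table — without shipping or requiring any real data.  All
randomness flows from explicit integer seeds through per-record generators,
so outputs are byte-identical across runs and platforms.

Synthetic labels are pronounceable stems plus vaccine-domain suffixes
("… vaccine", "… conjugate vaccine", product-style trade names); no real
trademarks are emitted beyond structural mimicry.
"""
from __future__ import annotations

import string
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._text import fold
from .evaluation import OOV_ID, GoldStandard
from .ontology import Concept, ConceptGraph

_CONSONANTS = list("bdfglmnprstvz")
_VOWELS = list("aeiou")
_MODIFIERS = ("conjugate", "subunit", "inactivated", "recombinant", "live attenuated")
_PRODUCT_SUFFIXES = ("vax", "rix", "mune", "gen", "flor", "teq")
_DOSE_TOKENS = ("0.5 mL", "1.0 mL", "10 mcg", "25 mcg", "2 doses", "lot 12")


@dataclass
class NoiseConfig:
    """Probabilities of the noise phenomena injected into mentions."""

    p_product_parenthetical: float = 0.15
    p_placebo_suffix: float = 0.10
    p_multi_concept: float = 0.10
    p_abbreviation: float = 0.10
    p_dose_noise: float = 0.20
    p_misspell: float = 0.05
    oov_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_product_parenthetical",
            "p_placebo_suffix",
            "p_multi_concept",
            "p_abbreviation",
            "p_dose_noise",
            "p_misspell",
            "oov_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


class MentionEntry(NamedTuple):
    mention_id: str
    nct_id: str
    mention: str


def _stem(rng: np.random.Generator, n_syllables: int | None = None) -> str:
    n = int(n_syllables or rng.integers(2, 4))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n)
    )


def _fresh(rng: np.random.Generator, make, used: set[str]) -> str:
    while True:
        cand = make()
        if fold(cand) not in used:
            used.add(fold(cand))
            return cand


def is_product(concept: Concept) -> bool:
    """Product-style concepts are vaccine terms whose label is a trade name."""
    return concept.is_vaccine and "vaccine" not in fold(concept.label).split()


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def make_ontology(
    n_vaccine: int = 80,
    n_distractor: int = 20,
    branching: int = 3,
    seed: int = 0,
) -> ConceptGraph:
    """Build a synthetic concept DAG: a vaccine subtree plus distractors.

    The vaccine subtree has ``n_vaccine`` concepts under a root labelled
    "vaccine", with a guaranteed chain of depth 3 (when sizes allow), labels
    keyed to depth ("<stem> vaccine" → "<stem> <modifier> vaccine" → trade-
    style product names), occasional second parents (DAG), and synthetic
    synonyms (initials, ®-suffixed product forms).  ``n_distractor``
    non-vaccine concepts (assays, adjuvants, antigens) hang under a separate
    root.  Deterministic per seed.
    """
    if n_vaccine < 1:
        raise ValueError("n_vaccine must be >= 1")
    if n_distractor < 0 or branching < 1:
        raise ValueError("n_distractor must be >= 0 and branching >= 1")
    rng = np.random.default_rng([int(seed), 101])
    used: set[str] = set()
    concepts: list[Concept] = []
    depth: dict[str, int] = {}
    children: dict[str, int] = {}

    def new_id() -> str:
        return f"VX:{len(concepts) + 1:07d}"

    def label_for(d: int) -> str:
        if d == 1:
            return _fresh(rng, lambda: f"{_stem(rng)} vaccine", used)
        if d == 2:
            return _fresh(
                rng,
                lambda: f"{_stem(rng)} {_MODIFIERS[rng.integers(len(_MODIFIERS))]} vaccine",
                used,
            )
        return _fresh(
            rng,
            lambda: (_stem(rng) + _PRODUCT_SUFFIXES[rng.integers(len(_PRODUCT_SUFFIXES))]).capitalize(),
            used,
        )

    def add(label: str, parents: tuple[str, ...], is_vaccine: bool) -> str:
        cid = new_id()
        syns: list[str] = []
        if is_vaccine and parents:
            d = depth[parents[0]] + 1
            if d >= 3 and rng.random() < 0.4:
                syns.append(f"{label}®")  # product form with a registration glyph
            elif rng.random() < 0.25:
                toks = label.split()
                if len(toks) >= 2:
                    abbr = "".join(t[0] for t in toks).upper()
                    if fold(abbr) not in used:
                        syns.append(abbr)
                        used.add(fold(abbr))
        concepts.append(Concept(cid, label, tuple(syns), parents, is_vaccine))
        depth[cid] = depth[parents[0]] + 1 if parents else 0
        children[cid] = 0
        for p in parents:
            children[p] += 1
        return cid

    root = add("vaccine", (), True)
    used.add(fold("vaccine"))
    vaccine_ids = [root]
    # guaranteed depth-3 chain
    chain_parent = root
    for _ in range(min(3, n_vaccine - 1)):
        chain_parent = add(label_for(depth[chain_parent] + 1), (chain_parent,), True)
        vaccine_ids.append(chain_parent)
    while len(vaccine_ids) < n_vaccine:
        open_slots = [c for c in vaccine_ids if children[c] < branching and depth[c] < 3]
        pool = open_slots or [c for c in vaccine_ids if depth[c] < 3] or vaccine_ids
        parent = pool[rng.integers(len(pool))]
        parents = [parent]
        if rng.random() < 0.1:  # occasional second parent → DAG, never a cycle
            others = [c for c in vaccine_ids if c != parent and depth[c] <= depth[parent]]
            if others:
                parents.append(others[rng.integers(len(others))])
        vaccine_ids.append(add(label_for(depth[parent] + 1), tuple(parents), True))

    if n_distractor > 0:
        droot = add("immunization assay", (), False)
        kinds = ("assay", "adjuvant", "antigen", "antiserum")
        for _ in range(n_distractor - 1):
            lbl = _fresh(rng, lambda: f"{_stem(rng)} {kinds[rng.integers(len(kinds))]}", used)
            add(lbl, (droot,), False)
    return ConceptGraph(concepts)


# ---------------------------------------------------------------------------
# mentions + gold standard
# ---------------------------------------------------------------------------

def make_mentions(
    graph: ConceptGraph, n: int = 200, cfg: NoiseConfig | None = None
) -> tuple[list[MentionEntry], GoldStandard]:
    """Generate *n* noisy mentions with gold mappings.

    Each mention derives from a vaccine concept; with the configured
    probabilities it gets a product parenthetical (gold becomes the product
    concept), is joined with a second concept (gold lists both ids), has the
    source label replaced by its initials, gains a " Placebo" suffix (gold
    unchanged — a placebo is annotated as the vaccine itself), gains dose/lot
    tokens, or has one character replaced.  A fraction ``oov_rate`` of
    mentions use labels absent from the graph and carry the OOV sentinel as
    gold.  Each mention draws from its own seeded generator, so gold
    assignments are invariant to changes in the purely textual noise rates.
    """
    cfg = cfg or NoiseConfig()
    sources = sorted(
        cid for cid in graph if graph[cid].is_vaccine and graph[cid].parent_ids
    )
    if not sources:
        raise ValueError("graph has no non-root vaccine concepts")
    products: dict[str, list[str]] = {cid: [] for cid in sources}
    for cid in sources:
        if is_product(graph[cid]):
            for p in graph[cid].parent_ids:
                if p in products:
                    products[p].append(cid)
    known = {fold(name) for _, name in graph.iter_names()}

    entries: list[MentionEntry] = []
    mapping: dict[str, frozenset[str]] = {}
    mentions_text: dict[str, str] = {}
    for i in range(n):
        rng = np.random.default_rng([int(cfg.seed), 7, i])
        # --- gold-determining draws first -------------------------------
        if rng.random() < cfg.oov_rate:
            label = _fresh(rng, lambda: f"{_stem(rng, 3)} vaccine", set(known))
            mention = label
            gold: frozenset[str] = frozenset({OOV_ID})
            source_label = label
        else:
            cid = sources[rng.integers(len(sources))]
            source_label = graph[cid].label
            mention = source_label
            gold = frozenset({cid})
            if rng.random() < cfg.p_product_parenthetical and products[cid]:
                prod = products[cid][rng.integers(len(products[cid]))]
                mention = f"{source_label} ({graph[prod].label})"
                gold = frozenset({prod})
            if rng.random() < cfg.p_multi_concept:
                second = sources[rng.integers(len(sources))]
                if second == cid and len(sources) > 1:
                    second = sources[(sources.index(cid) + 1) % len(sources)]
                if second != cid:
                    mention = f"{mention}, {graph[second].label}"
                    gold = gold | {second}
        # --- purely textual noise (gold unchanged) ----------------------
        if rng.random() < cfg.p_abbreviation:
            toks = source_label.split()
            if len(toks) >= 2:
                mention = mention.replace(source_label, "".join(t[0] for t in toks).upper(), 1)
        if rng.random() < cfg.p_placebo_suffix:
            mention = f"{mention} Placebo"
        if rng.random() < cfg.p_dose_noise:
            mention = f"{mention} {_DOSE_TOKENS[rng.integers(len(_DOSE_TOKENS))]}"
        if rng.random() < cfg.p_misspell:
            pos = [j for j, ch in enumerate(mention) if ch.isalpha()]
            if pos:
                j = pos[rng.integers(len(pos))]
                repl = string.ascii_lowercase[rng.integers(26)]
                if repl != mention[j].lower():
                    mention = mention[:j] + repl + mention[j + 1 :]
        mid = f"M{i + 1:04d}"
        entries.append(MentionEntry(mid, f"NCT{90000000 + i}", mention))
        mapping[mid] = gold
        mentions_text[mid] = mention
    return entries, GoldStandard(mapping, mentions_text)


def write_mention_entries(entries: list[MentionEntry], path) -> None:
    """Write a mentions TSV: mention_id, nct_id, mention."""
    pd.DataFrame(entries, columns=["mention_id", "nct_id", "mention"]).to_csv(
        path, sep="\t", index=False
    )


def read_mention_entries(path) -> list[MentionEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [MentionEntry(r.mention_id, r.nct_id, r.mention) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# interventions table
# ---------------------------------------------------------------------------

def make_interventions(
    entries: list[MentionEntry], n_background: int = 300, seed: int = 0
) -> pd.DataFrame:
    """Emulate a registry interventions table around the generated mentions.

    Mention rows are typed ``Biological``; background rows mix other
    intervention types (drugs, devices, procedures) and Biological
    non-vaccine rows (antibodies, antisera, bare placebo).  Row order is a
    seeded shuffle; deterministic per seed.
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    rng = np.random.default_rng([int(seed), 23])
    rows: list[tuple[str, str, str]] = [
        (e.nct_id, "Biological", e.mention) for e in entries
    ]
    backgrounds = (
        ("Drug", lambda: f"{_stem(rng)}umab {_DOSE_TOKENS[rng.integers(len(_DOSE_TOKENS))]}"),
        ("Drug", lambda: f"{_stem(rng)}inib"),
        ("Biological", lambda: f"{_stem(rng)} monoclonal antibody"),
        ("Biological", lambda: "Placebo"),
        ("Biological", lambda: f"{_stem(rng)} antiserum"),
        ("Device", lambda: f"{_stem(rng)} autoinjector"),
        ("Procedure", lambda: f"{_stem(rng)} infusion"),
        ("Other", lambda: "vaccine diary card review"),  # non-Biological, keyword present
    )
    for j in range(n_background):
        kind, make = backgrounds[rng.integers(len(backgrounds))]
        rows.append((f"NCT{80000000 + j}", kind, make()))
    order = rng.permutation(len(rows))
    shuffled = [rows[int(i)] for i in order]
    return pd.DataFrame(
        {
            "id": range(1, len(shuffled) + 1),
            "nct_id": [r[0] for r in shuffled],
            "intervention_type": [r[1] for r in shuffled],
            "name": [r[2] for r in shuffled],
        }
    )


def write_interventions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
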