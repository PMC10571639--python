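# Methods

## Problem setting

The toolkit normalizes free-text vaccine mentions — as they appear in the
`interventions` table of a clinical-trial registry dump — to concepts of a
vaccine ontology given as a DAG of (id, label, synonyms, is_a-parents)
records.  The pipeline has five stages: vocabulary preparation, mention
mining, candidate retrieval, ensemble fusion with a string-matching
promotion rule, and evaluation with an error taxonomy.  Every stage is
usable on its own; `pipeline.run_pipeline` wires them together.

## Vocabulary model

Concepts form a directed acyclic graph with edges child → parent.  Labels
are non-empty and synonyms never duplicate the label; every parent id must
resolve, and cycles are rejected with the offending cycle listed.  The
all-names index folds names by stripping ®/™ glyphs, Unicode-casefolding,
and collapsing whitespace — product names such as "FluMist ®" then compare
equal to "flumist".

Only a minimal OBO subset is honored on load (`[Term]` stanzas with `id`,
`name`, `synonym`, `is_a`; obsolete terms skipped); everything else is
ignored.  The TSV dialect (`id`, `label`, pipe-separated `synonyms` and
`parents`, `is_vaccine` 0/1) round-trips exactly and is what the synthetic
generator writes.

**Vaccine filtering.**  Real vaccine ontologies mix vaccine and
non-vaccine terms (assays, adjuvants, antigens).  Curation is modelled as
either a subtree closure (keep the named roots and everything below them)
or a label predicate, both idempotent; `is_vaccine` is set on retained
concepts and parent links are restricted to the retained set.

**Relation classification.**  For a gold/predicted pair the relation is:
`exact` (equal ids), `oov` (prediction absent from the graph),
`parent_child` (shortest directed is_a path of length 1, either
direction), `ancestor_descendant` (shortest path exactly 2), `sibling`
(≥1 shared parent and no directed path), `semantic` (everything else,
including paths spanning more than two levels and unrelated pairs).  The
two-level boundary between `ancestor_descendant` and `semantic` is a
declared convention: "spanning more than two levels" has no unique formal
reading, and shortest-path-on-a-DAG with the 1/2/>2 split is the one
consistent partition of all ordered pairs.  Sibling checks *any* shared
parent, not all parents.

## Mention mining

Two passes over the interventions table, both restricted to rows whose
`intervention_type` is exactly the literal `Biological` (the registry's
own casing):

1. vocabulary pass — the case-folded row name contains any concept name
   (label *or* synonym) as a contiguous substring, mirroring SQL
   `position(lower(x) IN lower(name)) > 0`;
2. keyword pass — the name contains a keyword (default `vaccine`),
   mirroring `lower(name) LIKE '%vaccine%'`.

Matching is raw substring, not token-boundary, for fidelity to the SQL
semantics.  The union is deduplicated on the case-folded,
whitespace-collapsed name; within a duplicate group the lexicographically
smallest raw form is kept and output is sorted by the dedupe key, making
the corpus independent of row order.  Stage counts are kept in a
PRISMA-style report whose inequalities (n_unique ≤ n_union ≤ n_query1 +
n_query2; n_query1, n_query2 ≤ n_biological ≤ n_total) are enforced at
construction.

When one row matches several vocabulary names, a TF-IDF matcher over
character 3-grams of the case-folded strings (smooth idf, L2-normalized,
cosine) picks the single best name; ties break by longer name, then
lexicographic order.  Character n-grams were chosen over word tokens
because intervention names carry dose/punctuation noise that destroys
token identity but leaves most character trigrams intact.

`emit_sql` renders both queries as text for users with a live database;
it interpolates labels *and* synonyms (so the SQL has the same semantics
as the in-memory scan) with quote escaping.

## Candidate retrieval

An encoder backend maps strings to unit-L2 row vectors and must be
deterministic.  The shipped backend is a TF-IDF character n-gram
vectorizer (default 3-grams) fitted on the vocabulary names; inputs are
case-folded with the same normalization as the all-names index.  Strings
shorter than the n-gram width encode to the zero vector and simply score
zero everywhere; this affects only 2–3-character abbreviation synonyms.

The index holds one vector per (concept, name) pair.  A concept's score
for a mention is the **maximum** cosine over its name entries
(max-pooling — the standard entity-linking convention; adding a synonym
can then never lower a concept's score).  Retrieval is an exact
brute-force scan — at vocabulary scales of 10³–10⁴ names this costs one
matrix-vector product — with ties broken by concept id so results are
independent of entry order.  Cosine scores are quantized to 12 decimals
before ranking: mathematically equal entries (e.g. two equally distant
labels) must stay tied under the id tie-break regardless of how the BLAS
accumulates the dot products.  Default K = 10, matching the Top-10
reporting depth.

Transformer encoders enter only through the backend contract; no training
loop ships.  A typical fine-tuning recipe for a domain BERT used this way
is 1 epoch, batch 256, learning rate 2e-5, max sequence length 25; raw
text should be passed to such backends (the fallback backend folds case
itself).

## Ensemble fusion and the SM-Rule

Per-model candidate lists are truncated to depth K and combined as a
weighted sum of per-model contributions:

- `score`: the raw cosine;
- `scale`: cosine min-max rescaled to [0, 1] within that model's top-K
  list for that mention (per-list, not corpus-wide, so models with
  different score ranges become comparable per mention; a degenerate list
  with max == min contributes 1 for every present candidate);
- `rank`: Borda points K − rank + 1 (the simplest order-consistent
  "ranking score"; the choice is recorded in the config so reciprocal
  rank or others can be added).

Concepts absent from a model's list contribute 0 under all metrics.
Models are folded in sorted-name order so float summation is independent
of mapping iteration order.  Final ties break by concept id.  With a
single positively weighted model, all three metrics reproduce that
model's ordering exactly (min-max and Borda are monotone within a list).

Default weights are proportional to per-model Top-1 accuracy on a
validation corpus, restricted to the best three models ("better models
get more weight"); explicit weights override.

The SM-Rule scans all labels and synonyms for case-folded substring
occurrence inside the mention, picks the longest matched name (ties:
lexicographically smallest folded name, then smallest concept id), and
moves its concept to rank 1 — inserting it if absent — while preserving
the relative order of the other candidates.  It reorders rather than
rescores, so fused scores are untouched and the rule is idempotent.  An
inserted concept carries score 0, so candidate scores are non-increasing
in rank only before promotion.

## Evaluation

Acc@n is mention-level: the fraction of mentions with at least one gold
id among the top min(n, list length) candidates.  Multi-valued gold sets
use any-match — the least-assumption reading of multi-concept
annotations.  The acc vector is monotone in n by construction and
asserted on every run.

Each rank-1 miss gets exactly one error type, assigned by fixed priority:

1. `oov` — no gold id is in the vocabulary (gold sets may carry the
   sentinel id `OOV`, which the synthetic generator emits for mentions
   drawn from outside the graph);
2. `ner_multi_concept` — the gold set has ≥2 concepts;
3. `disambiguation` — a gold id appears at rank 2..K;
4. `hierarchy_parent_child` / `hierarchy_ancestor_descendant` /
   `hierarchy_sibling` — from the relation between the top prediction and
   the nearest gold concept (nearest = best relation under exact >
   parent_child > ancestor_descendant > sibling > semantic);
5. linguistic heuristics, in order `abbreviation` (an all-caps 2–6-letter
   mention token equals the initials of a gold label), `spelling` (some
   mention/gold token pair at edit distance 1–2), `stemming` (tokens
   sharing a ≥4-character prefix but differing), `ner_noise` (dose/
   unit/lot patterns in the mention);
6. `semantic` — the residual: deep (>2-level) or unrelated confusions
   with no linguistic signal.

The `semantic` class is deliberately last: it is the relation
classifier's catch-all, and placing it above the linguistic heuristics
would make them unreachable.  All heuristics can be replaced per-call via
hooks, and heuristics can be disabled wholesale, which reduces the
taxonomy to the relational core.

## Synthetic data generator

The generator emulates the *structure* of the real inputs, not their
statistics:

- **Ontology** (default 80 vaccine + 20 distractor concepts, branching 3):
  a vaccine subtree with a guaranteed depth-3 chain, depth-keyed labels
  ("<stem> vaccine" → "<stem> <modifier> vaccine" → trade-style product
  names), occasional second parents (DAG), and synthetic synonyms —
  initials, and ®-suffixed product forms that exercise glyph stripping.
  Distractors (assays, adjuvants, antigens) hang under a separate root.
  Labels are pronounceable consonant-vowel stems; no real trademark is
  reproduced.
- **Mentions** (default 200): each derives from a vaccine concept and
  with configured probabilities gains a product parenthetical (gold
  becomes the product concept — product names are preferred in
  annotation), a second concept joined by ", " (gold lists both), an
  initials abbreviation, a " Placebo" suffix (gold unchanged — a placebo
  arm is annotated as the vaccine itself), dose/lot tokens, or a
  single-character misspelling; a fraction (default 5%) is drawn from
  outside the graph and carries the `OOV` sentinel.  Default rates
  (15% product, 10% placebo, 10% multi-concept, 10% abbreviation, 20%
  dose noise, 5% misspelling) roughly mirror the relative prevalence of
  these phenomena in registry intervention names.  Each mention uses its
  own seeded generator with gold-determining draws taken before noise
  draws, so changing a purely textual noise rate never changes the gold
  assignment — paired-run comparisons stay aligned.
- **Interventions table** (default 300 background rows): mention rows
  typed `Biological` plus shuffled background rows (drugs with dose
  tokens, monoclonal antibodies, bare "Placebo", devices, and a
  non-Biological row containing the word "vaccine" to exercise the type
  gate).

Everything is a pure function of its integer seed; repeated runs are
byte-identical.  What passing tests on this data do *not* show: coverage
of real AACT text distributions, multilingual mentions, real VO
granularity quirks, or encoder robustness beyond character-level noise —
transformer backends on real data remain the user's responsibility.

## Pipeline defaults and problem sizes

`run_pipeline` uses a 100-concept graph, 200 mentions, a 500-row
interventions table, and two char-n-gram backends ((3,3) and (2,4)) as
the model pool; fusion weights come from a 200-mention validation corpus
generated with an offset seed.  These sizes exercise every noise branch
and every code path while keeping a full run in a few seconds, which is
also the scale the acceptance script reports at.  Evaluation runs on the
generated mention corpus (for which gold exists by construction); the
extraction stage is reported through its PRISMA counts.

## Known limitations

- At default noise the SM-Rule can *lower* Acc@1 slightly: for
  product-parenthetical mentions "generic label (Product)" the gold is
  the product concept but the generic label is the longer verbatim match,
  so the rule promotes the generic parent.  This is inherent to
  longest-match promotion; under placebo/dose-only noise the rule is
  exact (Acc@1 = 1.0) and it never hurts there.
- Absolute accuracies on synthetic corpora are not comparable to results
  on expert-annotated registry data; only the relative behavior of
  metrics and rules is meaningful.
- The OBO reader handles the minimal tag subset only; OWL reasoning,
  cross-references and relationship types other than is_a are out of
  scope.
- No approximate nearest-neighbor index: retrieval is exact by contract,
  which is the right trade-off up to ~10⁵ name entries but not beyond.
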