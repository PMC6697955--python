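# Methods

## The mapping model

The package maps mention-level anatomical related entities to a
position-based body-part ontology through a three-stage cascade:
normalization, direct lookup, and knowledge-base candidate scoring. The
stages are strictly ordered — the knowledge base is consulted only when
direct lookup fails — so enabling later stages can extend but never alter
the decisions of earlier ones (this "cascade soundness" is asserted by
tests on every synthetic corpus).

### Ontology

The Tree of Human Body Parts is a forest: nine positional top-level
regions (head, neck, chest, abdomen, pelvis, back, hip, extremity,
trunk), organs and tissues below. Conventions encoded in the packaged
data:

* position over function — entities are filed where they sit ("carotid
  artery" is an alias of *neck*); tissues distributed through the whole
  body (nerve, blood, bone, muscle, skin, vein, artery) are children of
  *trunk*;
* results live on the lowest layer that names the entity — "mitral
  valve" is an alias of *heart*, not a chest-level term;
* one alias maps to exactly one node; collisions are a load-time error.

The packaged tree (61 nodes) covers every part and alias the mapping
conventions require plus a conventional anatomical expansion (ENT
structures under neck, digestive organs under abdomen, joint/limb
structures under the extremities). It is a hand-authored artifact:
no UMLS/SNOMED-CT/FMA import, no claim of completeness relative to any
external release. The file format is a flat JSON array of
`{id, formal_name, aliases, parent}` records — diffable, order-stable,
round-trips exactly.

### Text pipeline

One pipeline serves mentions, ontology aliases and explanation prose:
lowercase → tokenize on non-alphanumeric boundaries → drop stopwords →
singularize → Porter-stem. Matching therefore always compares
identically processed token sequences. Details:

* the Porter stemmer is implemented in-package (the classic 1980
  algorithm, verified against its published example vectors); tokens
  with digits or length ≤ 2 pass through unchanged, keeping
  abbreviations like "abd" or "le" stable;
* singularization precedes stemming and handles irregular plurals
  (feet → foot) plus Latin-style `-is/-us/-as + es` forms
  (pelvises → pelvis) that suffix stripping alone would mangle;
* the stopword list is a small fixed clinical-English list shipped
  in-repo and configurable by path; stopwords are removed before
  positional stripping;
* every alias-index key is a fixed point of the stemmer (tested), so
  lookups are stable under re-normalization.

### Positional words

The positional vocabulary (left/right, upper/lower, bilateral(ly),
proximal/distal, anterior/posterior, medial/lateral and related spatial
terms) is keyed by stemmed surface and maps to a canonical adjective
(bilaterally → bilateral). Stripping peels positional tokens from the
*edges* of the token sequence and stops as soon as the remainder names
an ontology part exactly: this protects part names that begin with a
positional word ("lower extremity", and "left lower extremity" →
positional *left* + part *lower extremity*). Interior positional tokens
are deliberately left in place; no such part names exist in the packaged
data. After mapping, canonical positionals are prefixed to the formal
name, for knowledge-base results as well as direct ones (uniform
treatment keeps labels comparable across stages).

### Abbreviations

Document-local evidence beats the global table: if the mention carries a
coreference chain, a longer chain member whose word initials spell the
abbreviation in order, or which begins with the abbreviation, provides
the full form. Otherwise the shipped dictionary applies; entries may
carry several full forms (HEENT → five parts), and all resolved forms
become parts of one multi-part mapping. When a mention's core resolves
directly *and* expansions exist, direct resolution wins (logged). No
word-sense disambiguation of ambiguous abbreviations is attempted.

### Knowledge-base scoring

For a term with no direct match, an explanation text is fetched (query
order: normalized core, then raw surface — fixture filenames use raw
terms, so the fallback matters), preprocessed with the shared pipeline,
and scanned left-to-right with longest-match-wins over multi-token
aliases; matches of different aliases of one part pool into a single
occurrence list. Candidate *n* with occurrence offsets in the filtered
stream gets

    Score(n) = a · f(D(n)) + b · f(F(n))

* `D(n)` — by default the **mean** of the candidate's offsets (the
  "average distance from the onset" reading); `first_offset` and
  `matched_rank` modes are provided because the distance definition
  admits more than one reading, and the choice is worth exploring
  rather than hard-wiring;
* `f(D) = cos(D · (π/2) / maxD)` for `maxD > 1`, `1` when `maxD = 1`,
  `0` when `maxD = 0`, where `maxD` is the largest `D` among candidates;
  the transform maps distances into [0, 1], decreasing. The degenerate
  `maxD = 0` case (every candidate at the onset) zeroes the distance
  term and lets frequency decide;
* `f(F) = F(n)`, multiplied by 2.5 for the single candidate whose
  earliest occurrence is minimal ("first entity"); offsets are unique
  per token span, so the first candidate is always well defined;
* defaults `a = 15`, `b = 1`, `first_multiplier = 2.5`. These are
  shipped constants; no re-estimation against any clinical corpus is
  attempted (an optional exploration is possible by constructing
  `ScoringParams` directly). Setting `algorithm="distance"` (b = 0) or
  `"frequency"` (a = 0) recovers the single-factor variants.

Candidates sort by descending score; exact ties (absolute tolerance
1e-9) break to the deeper ontology node (consistent with
lowest-layer-wins), then earliest occurrence, then lexicographic id —
fully deterministic. The head of the list is the mapping.

An independently written brute-force scorer (`anatomap.oracle`, no code
shared with `anatomap.scoring`) recomputes scores straight from raw
offset lists; ranker-vs-oracle argmax agreement is asserted at 100% on
1,000 seeded synthetic explanations.

### Knowledge sources

The fixture source (directory of `.txt` files, optional `index.tsv`) is
the reference source: byte-deterministic, offline, used by the whole
test suite. The live source queries the Wikipedia REST API for the lead
extract (configurable to full plain text), treats disambiguation pages
as misses, and raises a transport error (distinct from a miss) on
network failure. Live content drifts; nothing reproducible depends on
it. Per-run caching makes repeated terms cost one lookup.

Scored text is the *lead* extract by default: the opening prose of an
encyclopedia entry is where the defining anatomical location appears,
and distance-from-onset is most meaningful there. Plain prose only — no
markup, links or infoboxes.

## Evaluation

Micro-averaged P/R/F1 over (mention_id, part_id) pairs: a predicted
pair in gold is a true positive, a predicted pair not in gold a false
positive, a gold pair never predicted a false negative. Pair counting
handles multi-part abbreviations gracefully (each part is one pair). An
unmatched prediction asserts nothing: it contributes no pairs and is
penalized only through the false negatives it leaves. Matching is by
part id by default; `strict_labels=True` compares full
positional-prefixed labels instead.

## Synthetic data

The generator emulates the *structure* of the mapping problem, not
clinical prose style:

* **explanations** place single-token part names at exact offsets in a
  filler stream (filler vocabulary screened against the alias index;
  no stopwords emitted, so planted offsets equal post-filter offsets).
  Every emitted explanation is re-preprocessed, re-scanned and re-scored
  by the brute-force oracle before release; a spec whose intended winner
  loses is rejected with an error, never silently adjusted;
* **corpora** mix mention categories — formal names, aliases, naive
  plurals, positional prefixes, dictionary abbreviations, the
  multi-part abbreviation, and knowledge-base-only terms (invented
  digit-bearing tokens with generated explanations, 35% weight) — plus
  a `noise` fraction (floor of `noise · n`) of terms with no entry
  anywhere, whose gold is empty. The first mentions cycle through every
  category once so small corpora exercise the whole cascade; everything
  is reproducible from the seed, and corpus writes are byte-identical
  across runs.

What passing on this data does and does not show: it validates the
mechanics (normalization, matching, scoring, cascade ordering,
evaluation) under controlled conditions where gold is provable. It does
not estimate real-corpus accuracy — real discharge summaries add
misspellings, ambiguous abbreviations, special-character forms
("cad/chf", "hf-cells"), and explanation texts whose first-named part is
not the right answer. The benchmark ablation (string-match baseline <
+normalization ≤ full pipeline, with the full pipeline perfect at zero
noise) reproduces the expected *direction* of improvement, not any
real-corpus magnitude.

## Problem sizes and numerics

Default benchmark sizes: 200-mention corpora for ablation comparisons,
500 for cascade-soundness sweeps, 1,000 explanations for oracle
agreement — large enough that every category appears many times while
the full suite stays interactive. Scores are IEEE doubles; the only
comparison sensitive to rounding is exact-tie detection, handled with
the 1e-9 absolute tolerance. Degenerate inputs are contracts, not
surprises: empty occurrence lists and `D > maxD` raise; an empty
candidate set ranks to an empty list (unmatched); a purely positional
mention ("bilateral") normalizes to an empty core and is unmappable.

## Known limitations

* Interior positional words in multi-word non-part mentions are not
  stripped.
* One mention maps to one part through the knowledge-base branch (the
  top-ranked candidate only); genuinely multi-site entities ("renal
  vein") resolve to a single node.
* The coreference full-form heuristic (initials-in-order or prefix) is
  intentionally simple and will miss reordered or partial expansions.
* The abbreviation dictionary is small and unambiguous by design;
  ambiguous short forms are out of scope without a disambiguation
  component.
* Special-character compounds ("cad/chf", "hf-cells") split at the
  separator and map — or fail — token by token; no repair is attempted.
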