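"""Synthetic ontology-mapping benchmarks: planted explanations and corpora.

Real discharge summaries are access-restricted, so every offline test
runs against data built here: explanation texts in which body-part
names occur at *controlled* token offsets and frequencies (so the
score argmax is known by construction and verified by the independent
brute-force scorer), and whole corpora mixing direct-matchable
mentions (formal names, aliases, plurals, positional prefixes,
abbreviations) with knowledge-base-only mentions backed by generated
explanations. A configurable noise fraction of mentions has no
knowledge-base entry at all and is gold-unmatched.

Everything is reproducible from a seed; generated gold is never trusted
blindly — each planted explanation is re-scanned and re-scored before
it is emitted, and generation fails loudly if a distractor would win.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .kb import Explanation, preprocess_explanation, slugify
from .normalize import Mention, stem_and_clean
from .ontology import Ontology, find_matches_in_text, resolve_term
from .oracle import brute_force_best
from .scoring import ScoringParams

__all__ = [
    "PlantSpec",
    "GenerationError",
    "SyntheticCorpus",
    "generate_explanation",
    "generate_corpus",
    "random_plant_spec",
    "default_filler_vocab",
]

# tokens guaranteed stable under the cleaning pipeline and disjoint from
# every ontology alias stem (checked again at generation time)
_FILLER = (
    "zelkova", "quill", "ember", "garnet", "willow", "basalt", "meadow",
    "copper", "violet", "harbor", "lantern", "pebbl", "timber", "crimson",
    "saffron", "indigo", "marble", "cobalt", "amber", "juniper",
)


class GenerationError(RuntimeError):
    """A plant spec whose intended winner would not actually win."""


@dataclass(frozen=True)
class PlantSpec:
    """Where each candidate must appear in a generated explanation.

    Offsets are positions in the post-stopword token stream; the
    generator emits no stopwords, so they are also raw positions. All
    offset lists must be pairwise disjoint, and the target must beat
    every distractor under the stated scoring parameters.
    """

    target_part: str
    target_offsets: tuple[int, ...]
    distractor_parts: tuple[str, ...] = ()
    distractor_offsets: tuple[tuple[int, ...], ...] = ()
    filler_vocab: tuple[str, ...] = _FILLER
    seed: int = 0


def default_filler_vocab() -> tuple[str, ...]:
    return _FILLER


def _single_token_name(onto: Ontology, part_id: str) -> str:
    toks = stem_and_clean(onto[part_id].formal_name)
    if len(toks) != 1:
        raise GenerationError(
            f"part {part_id!r}: planting needs a single-token formal name"
        )
    return onto[part_id].formal_name


def generate_explanation(
    spec: PlantSpec,
    params: ScoringParams | None = None,
    onto: Ontology | None = None,
    term: str = "synthetic term",
) -> tuple[Explanation, str]:
    """Emit prose realizing a :class:`PlantSpec`; returns (explanation, winner).

    The text is re-preprocessed and re-scored before returning: if the
    planted offsets do not survive the pipeline or the brute-force
    scorer elects a distractor, generation fails (the spec is rejected,
    never silently adjusted).
    """
    from .ontology import load_ontology

    onto = onto or load_ontology()
    params = (params or ScoringParams()).effective()
    rng = random.Random(spec.seed)

    planted: dict[int, str] = {}
    occurrences: dict[str, list[int]] = {}
    for part_id, offsets in (
        (spec.target_part, spec.target_offsets),
        *zip(spec.distractor_parts, spec.distractor_offsets),
    ):
        surface = _single_token_name(onto, part_id)
        for off in offsets:
            if off in planted:
                raise GenerationError(f"offset {off} planted twice")
            planted[off] = surface
        occurrences.setdefault(part_id, []).extend(offsets)

    filler = [
        w
        for w in spec.filler_vocab
        if tuple(stem_and_clean(w)) not in onto.alias_index
        and len(stem_and_clean(w)) == 1
    ]
    if not filler:
        raise GenerationError("filler vocabulary is empty after screening")

    length = max(planted) + 1 + rng.randrange(1, 4)
    tokens = [
        planted.get(i, rng.choice(filler)) for i in range(length)
    ]
    sentences = [
        " ".join(tokens[i : i + 12]).capitalize()
        for i in range(0, length, 12)
    ]
    raw_text = ". ".join(sentences) + "."

    # honesty checks: the pipeline must see exactly the planted layout,
    # and the independent scorer must elect the target
    processed = preprocess_explanation(raw_text)
    found = {
        o.part_id: list(o.offsets) for o in find_matches_in_text(onto, processed)
    }
    expected = {pid: sorted(offs) for pid, offs in occurrences.items()}
    if found != expected:
        raise GenerationError(
            f"planted occurrences not recovered: wanted {expected}, got {found}"
        )
    depths = {pid: onto.depth(pid) for pid in occurrences}
    winner = brute_force_best(
        occurrences,
        depths=depths,
        a=params.a,
        b=params.b,
        first_multiplier=params.first_multiplier,
        distance_mode=params.distance_mode,
        tie_break=params.tie_break,
    )
    if winner != spec.target_part:
        raise GenerationError(
            f"spec rejected: {winner!r} outscores target {spec.target_part!r}"
        )
    explanation = Explanation(
        term=term, raw_text=raw_text, tokens=processed, source="fixture"
    )
    return explanation, spec.target_part


def random_plant_spec(
    onto: Ontology,
    rng: random.Random,
    candidate_ids: Sequence[str] | None = None,
    n_distractors: int | None = None,
) -> PlantSpec:
    """Draw a random spec in which the target provably wins.

    The target is planted at the text onset with the highest frequency;
    distractors appear later and less often, so the combined score
    always elects the target (still verified downstream).
    """
    if candidate_ids is None:
        candidate_ids = sorted(
            pid
            for pid in onto.nodes
            if len(stem_and_clean(onto[pid].formal_name)) == 1
        )
    k = n_distractors if n_distractors is not None else rng.randrange(0, 3)
    chosen = rng.sample(list(candidate_ids), k + 1)
    target, distractors = chosen[0], chosen[1:]

    target_count = rng.randrange(2, 5)
    target_offsets = [0]
    cursor = 0
    for _ in range(target_count - 1):
        cursor += rng.randrange(2, 5)
        target_offsets.append(cursor)
    distractor_offsets = []
    for _ in distractors:
        offs = []
        for _ in range(rng.randrange(1, target_count)):
            cursor += rng.randrange(2, 5)
            offs.append(cursor)
        distractor_offsets.append(tuple(offs))
    return PlantSpec(
        target_part=target,
        target_offsets=tuple(target_offsets),
        distractor_parts=tuple(distractors),
        distractor_offsets=tuple(distractor_offsets),
        seed=rng.randrange(2**31),
    )


# ---------------------------------------------------------------------------
# corpus generation

_CATEGORIES = (
    "formal", "alias", "plural", "positional", "abbrev", "multi_abbrev", "kb"
)
_WEIGHTS = (0.12, 0.12, 0.12, 0.14, 0.10, 0.05, 0.35)

_POSITIONALS = ("left", "right", "bilateral")


@dataclass
class SyntheticCorpus:
    """A generated benchmark: mentions, gold mappings and fixture KB texts."""

    mentions: list[Mention]
    gold: dict[str, list[str]]
    kb_texts: dict[str, str]
    category_of: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "mentions.tsv", "w", encoding="utf-8", newline="") as fh:
            fh.write("doc_id\tmention_id\tstart\tend\tsurface\tcoref_chain_id\n")
            for m in self.mentions:
                fh.write(
                    f"{m.doc_id}\t{m.mention_id}\t{m.start}\t{m.end}\t"
                    f"{m.surface}\t{m.coref_chain_id or ''}\n"
                )
        with open(out / "gold.tsv", "w", encoding="utf-8", newline="") as fh:
            fh.write("mention_id\tpart_ids\n")
            for m in self.mentions:
                fh.write(f"{m.mention_id}\t{';'.join(self.gold[m.mention_id])}\n")
        kb_dir = out / "kb"
        kb_dir.mkdir(exist_ok=True)
        for term, text in sorted(self.kb_texts.items()):
            (kb_dir / (slugify(term) + ".txt")).write_text(
                text, encoding="utf-8"
            )


def _naive_plural(name: str) -> str:
    return name + ("es" if name.endswith(("s", "x", "z", "ch", "sh")) else "s")


def generate_corpus(
    n: int,
    onto: Ontology | None = None,
    seed: int = 0,
    noise: float = 0.0,
    params: ScoringParams | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticCorpus:
    """Generate an ``n``-mention benchmark corpus.

    ``noise`` is the fraction (by floor) of mentions that look like
    knowledge-base-only terms but have no entry anywhere: their gold
    mapping is empty (unmatched). The first mentions cycle through every
    category once so that small corpora still exercise the whole
    cascade; the rest are drawn by weight. Deterministic given ``seed``.
    """
    from .ontology import load_ontology

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    onto = onto or load_ontology()
    params = params or ScoringParams()
    rng = random.Random(seed)

    single_parts = sorted(
        pid
        for pid in onto.nodes
        if len(stem_and_clean(onto[pid].formal_name)) == 1
    )
    alias_pool = sorted(
        (pid, alias)
        for pid in onto.nodes
        for alias in onto[pid].aliases
        if stem_and_clean(alias)
    )
    abbrev_pool = []
    from .normalize import Resources

    resources = Resources.default()
    for key, forms in sorted(resources.abbreviations.items()):
        ids = []
        for form in forms:
            part = resolve_term(onto, stem_and_clean(form))
            if part is not None:
                ids.append(part.id)
        if len(forms) == 1 and len(ids) == 1:
            abbrev_pool.append((" ".join(key), ids))
    multi_abbrev = ("heent", ["head", "eye", "ear", "nose", "throat"])

    n_noise = int(noise * n)
    n_real = n - n_noise
    slots = ["noise"] * n_noise + [
        _CATEGORIES[i % len(_CATEGORIES)]
        if i < len(_CATEGORIES) and n_real >= len(_CATEGORIES)
        else rng.choices(_CATEGORIES, weights=_WEIGHTS, k=1)[0]
        for i in range(n_real)
    ]
    rng.shuffle(slots)

    mentions: list[Mention] = []
    gold: dict[str, list[str]] = {}
    kb_texts: dict[str, str] = {}
    category_of: dict[str, str] = {}

    for i, category in enumerate(slots):
        mid = f"m{i:05d}"
        doc = f"doc{i % 10:02d}"
        if category == "formal":
            pid = rng.choice(single_parts)
            surface, parts = onto[pid].formal_name, [pid]
        elif category == "alias":
            pid, alias = rng.choice(alias_pool)
            surface, parts = alias, [pid]
        elif category == "plural":
            pid = rng.choice(single_parts)
            surface, parts = _naive_plural(onto[pid].formal_name), [pid]
        elif category == "positional":
            pid = rng.choice(single_parts)
            pos = rng.choice(_POSITIONALS)
            if pos == "bilateral" and rng.random() < 0.5:
                surface = f"{_naive_plural(onto[pid].formal_name)} bilaterally"
            else:
                surface = f"{pos} {onto[pid].formal_name}"
            parts = [pid]
        elif category == "abbrev":
            key, ids = rng.choice(abbrev_pool)
            surface = key.upper() if rng.random() < 0.5 else key
            parts = list(ids)
        elif category == "multi_abbrev":
            key, ids = multi_abbrev
            surface = key.upper() if rng.random() < 0.5 else key
            parts = list(ids)
        elif category == "kb":
            term = f"proc{i:05d}x"
            spec = random_plant_spec(onto, rng, candidate_ids=single_parts)
            explanation, winner = generate_explanation(
                spec, params, onto, term=term
            )
            kb_texts[term] = explanation.raw_text
            surface, parts = term, [winner]
        else:  # noise: a term nothing knows about
            surface, parts = f"zq{i:05d}n", []
        mentions.append(
            Mention(
                doc_id=doc,
                mention_id=mid,
                start=0,
                end=len(surface),
                surface=surface,
            )
        )
        gold[mid] = parts
        category_of[mid] = category

    corpus = SyntheticCorpus(mentions, gold, kb_texts, category_of)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus
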