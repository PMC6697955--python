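"""Named-entity normalization for anatomical mentions.

Turns a raw surface span ("legs bilaterally", "HEENT", "left
extremities") into a canonical core term plus positional modifiers:

1. :func:`stem_and_clean` — lowercase, tokenize, drop stopwords,
   singularize plurals, Porter-stem;
2. :func:`strip_positional` — split off positional words (left, lower,
   bilateral, ...) to be re-attached to the final mapping result;
3. :func:`expand_abbreviation` — recover full forms from the mention's
   coreference chain (document-local evidence) or from a shipped
   abbreviation dictionary; multi-part abbreviations such as HEENT
   expand to several full forms.

All dictionary keys are stemmed with the same pipeline as the text, so
the two sides always meet in the same token space.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .porter import stem

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

__all__ = [
    "Mention",
    "NormalizedMention",
    "Resources",
    "InvalidMentionError",
    "tokenize",
    "singularize",
    "stem_and_clean",
    "strip_positional",
    "expand_abbreviation",
    "normalize_mention",
    "reattach_positional",
    "load_stopwords",
    "load_positional_vocab",
    "load_abbreviations",
    "load_coref_chains",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

_IRREGULAR_PLURALS = {
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "children": "child",
    "nuclei": "nucleus",
    "vertebrae": "vertebra",
}


class InvalidMentionError(ValueError):
    """Raised for mentions that violate the input contract (empty span)."""


@dataclass(frozen=True)
class Mention:
    """One anatomical related entity occurrence in a source document."""

    doc_id: str
    mention_id: str
    start: int
    end: int
    surface: str
    coref_chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidMentionError(
                f"mention {self.mention_id}: start must be < end"
            )
        if not self.surface:
            raise InvalidMentionError(
                f"mention {self.mention_id}: empty surface"
            )


@dataclass
class NormalizedMention:
    """A mention after cleaning, positional stripping and expansion.

    ``provenance`` records where the expansions came from: ``plain`` (no
    expansion applied), ``dictionary`` or ``coreference``. A mention that
    was purely positional has empty ``core_tokens`` and ``expansions``
    and is unmappable.
    """

    core_tokens: tuple[str, ...]
    positionals: tuple[str, ...] = ()
    expansions: tuple[tuple[str, ...], ...] = ()
    provenance: str = "plain"


@dataclass
class Resources:
    """The dictionaries consulted during normalization."""

    stopwords: frozenset[str]
    positional_vocab: dict[str, str]  # stemmed surface -> canonical form
    abbreviations: dict[tuple[str, ...], list[str]]
    coref_chains: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "Resources":
        """Packaged stopword/positional/abbreviation tables, no chains."""
        base = _importlib_resources.files("anatomap.data")
        return cls(
            stopwords=load_stopwords(Path(base / "stopwords.txt")),
            positional_vocab=load_positional_vocab(Path(base / "positional.tsv")),
            abbreviations=load_abbreviations(Path(base / "abbreviations.tsv")),
        )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "Resources":
        """Load stopwords.txt / positional.tsv / abbreviations.tsv and an
        optional coref_chains.tsv from a resource directory."""
        d = Path(directory)
        chains_path = d / "coref_chains.tsv"
        return cls(
            stopwords=load_stopwords(d / "stopwords.txt"),
            positional_vocab=load_positional_vocab(d / "positional.tsv"),
            abbreviations=load_abbreviations(d / "abbreviations.tsv"),
            coref_chains=(
                load_coref_chains(chains_path) if chains_path.exists() else {}
            ),
        )


# ---------------------------------------------------------------------------
# resource file loaders

def load_stopwords(path: str | Path) -> frozenset[str]:
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.strip().lower() for w in words if w.strip())


def load_positional_vocab(path: str | Path) -> dict[str, str]:
    """TSV (surface, canonical) -> mapping of *stemmed* surface to canonical."""
    vocab: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = stem(row["surface"].strip().lower())
            canonical = row["canonical"].strip().lower()
            if key in vocab and vocab[key] != canonical:
                raise ValueError(
                    f"{path}: positional surfaces {row['surface']!r} collide "
                    f"on stem {key!r} with different canonicals"
                )
            vocab[key] = canonical
    return vocab


def load_abbreviations(path: str | Path) -> dict[tuple[str, ...], list[str]]:
    """TSV (key, full_forms pipe-separated) keyed by stemmed token tuple."""
    table: dict[tuple[str, ...], list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = tuple(
                stem(t) for t in _TOKEN_RE.findall(row["key"].strip().lower())
            )
            forms = [f.strip() for f in row["full_forms"].split("|") if f.strip()]
            if key and forms:
                table[key] = forms
    return table


def load_coref_chains(path: str | Path) -> dict[tuple[str, str], list[str]]:
    """TSV (chain_id, doc_id, member_text) -> {(doc_id, chain_id): members}."""
    chains: dict[tuple[str, str], list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chains.setdefault(
                (row["doc_id"].strip(), row["chain_id"].strip()), []
            ).append(row["member_text"].strip())
    return chains


# ---------------------------------------------------------------------------
# the normalization pipeline

def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def singularize(token: str) -> str:
    """Heuristic plural -> singular; irregulars first, then suffix rules."""
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(
        ("ches", "shes", "sses", "xes", "zes", "ises", "uses", "ases")
    ):
        return token[:-2]
    if (
        token.endswith("s")
        and len(token) > 3
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


def stem_and_clean(
    surface: str, stopwords: frozenset[str] | None = None
) -> list[str]:
    """Lowercase, tokenize, drop stopwords, singularize, Porter-stem.

    This one pipeline is applied to mention text, ontology aliases and
    knowledge-base explanations alike, so every comparison in the
    package happens between identically preprocessed token sequences.
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    return [
        stem(singularize(tok))
        for tok in tokenize(surface)
        if tok not in stopwords
    ]


_STOPWORD_CACHE: frozenset[str] | None = None


def _default_stopwords() -> frozenset[str]:
    global _STOPWORD_CACHE
    if _STOPWORD_CACHE is None:
        base = _importlib_resources.files("anatomap.data")
        _STOPWORD_CACHE = load_stopwords(Path(base / "stopwords.txt"))
    return _STOPWORD_CACHE


def strip_positional(
    tokens: Sequence[str],
    vocab: dict[str, str],
    onto: "Ontology | None" = None,
) -> tuple[list[str], list[str]]:
    """Split positional modifiers off a cleaned token sequence.

    Returns ``(positionals, core)`` with positionals in their original
    order, mapped to canonical forms (bilaterally -> bilateral).
    Positional words are peeled from the edges only, and never when the
    remaining sequence already names an ontology part exactly — this
    protects names like "lower extremity" whose first token is itself a
    positional word.
    """
    toks = list(tokens)
    leading: list[str] = []
    trailing: list[str] = []
    while toks:
        if onto is not None and tuple(toks) in onto.alias_index:
            break
        if toks[0] in vocab:
            leading.append(vocab[toks[0]])
            toks.pop(0)
        elif toks[-1] in vocab:
            trailing.insert(0, vocab[toks[-1]])
            toks.pop()
        else:
            break
    return leading + trailing, toks


def _initials_match(abbrev: str, words: Sequence[str]) -> bool:
    return len(abbrev) == len(words) and all(
        w and w[0] == ch for ch, w in zip(abbrev, words)
    )


def expand_abbreviation(
    core: Sequence[str],
    resources: Resources,
    doc_id: str | None = None,
    coref_chain_id: str | None = None,
    surface: str | None = None,
) -> tuple[list[tuple[str, ...]], str]:
    """Recover full-form token sequences for an abbreviation-like core.

    Lookup order: (1) the mention's coreference chain — a longer chain
    member counts as the full form when the abbreviation's letters are
    the member's word initials in order, or a prefix of the member;
    (2) the abbreviation dictionary, whose entries may carry several
    full forms (multi-part abbreviations like HEENT).

    Returns ``(expansions, provenance)``; provenance is ``coreference``,
    ``dictionary`` or ``plain`` (no source applied, empty expansions).
    """
    abbrev = (surface or " ".join(core)).lower().replace(" ", "")
    abbrev = re.sub(r"[^a-z0-9]", "", abbrev)

    if doc_id is not None and coref_chain_id is not None and abbrev:
        members = resources.coref_chains.get((doc_id, coref_chain_id), [])
        for member in sorted(members, key=len, reverse=True):
            words = tokenize(member)
            joined = "".join(words)
            if joined == abbrev or not words:
                continue
            if _initials_match(abbrev, words) or (
                len(joined) > len(abbrev) and joined.startswith(abbrev)
            ):
                full = tuple(stem_and_clean(member, resources.stopwords))
                if full:
                    return [full], "coreference"

    forms = resources.abbreviations.get(tuple(core))
    if forms:
        expansions = []
        for form in forms:
            toks = tuple(stem_and_clean(form, resources.stopwords))
            if toks:
                expansions.append(toks)
        if expansions:
            return expansions, "dictionary"
    return [], "plain"


def normalize_mention(
    m: Mention,
    resources: Resources,
    onto: "Ontology | None" = None,
) -> NormalizedMention:
    """Full normalization: clean -> strip positionals -> expand.

    Idempotent on its own output: normalizing the rendered core again
    yields the same core tokens.
    """
    if not m.surface.strip():
        raise InvalidMentionError(f"mention {m.mention_id}: empty surface")
    tokens = stem_and_clean(m.surface, resources.stopwords)
    positionals, core = strip_positional(
        tokens, resources.positional_vocab, onto
    )
    expansions, provenance = expand_abbreviation(
        core,
        resources,
        doc_id=m.doc_id,
        coref_chain_id=m.coref_chain_id,
        surface=m.surface if len(core) <= 1 else None,
    )
    return NormalizedMention(
        core_tokens=tuple(core),
        positionals=tuple(positionals),
        expansions=tuple(expansions),
        provenance=provenance if expansions else "plain",
    )


def reattach_positional(
    positionals: Iterable[str], part_label: str
) -> str:
    """Prefix canonical positionals to a formal name: the final label.

    ``(["bilateral"], "lower extremity") -> "bilateral lower extremity"``.
    """
    prefix = " ".join(positionals)
    return f"{prefix} {part_label}" if prefix else part_label
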