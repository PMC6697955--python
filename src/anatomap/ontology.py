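"""The Tree of Human Body Parts (THBP) and matching against it.

The ontology is a forest of body-part nodes organised by anatomical
*position* (the nine top-level regions: head, neck, chest, abdomen,
pelvis, back, hip, extremity, trunk), each node carrying a canonical
formal name plus surface aliases (synonyms and abbreviations such as
"abd" for abdomen). Matching is always performed on lowercased,
Porter-stemmed token sequences so that inflectional variants unify.

Distributed tissues (nerve, blood, bone, ...) hang under *trunk*,
following the position-over-function convention: an entity is filed
where it sits in the body, and mapping results are the lowest layer of
the tree that names it (so "mitral valve" resolves to heart, not chest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .normalize import stem_and_clean

__all__ = [
    "BodyPart",
    "Ontology",
    "OccurrenceList",
    "OntologyError",
    "ValidationReport",
    "load_ontology",
    "packaged_thbp_path",
    "save_ontology",
    "resolve_term",
    "find_matches_in_text",
    "validate_ontology",
]

TokenSeq = tuple[str, ...]


class OntologyError(ValueError):
    """Raised for unparseable or invalid ontology files."""


@dataclass(frozen=True)
class BodyPart:
    """One node of the tree: a formal name, its aliases and its parent."""

    id: str
    formal_name: str
    aliases: tuple[str, ...]
    parent_id: str | None
    depth: int = 0


@dataclass
class OccurrenceList:
    """All occurrences of one body part in a preprocessed token stream.

    ``offsets`` are 0-based positions (of the first token of each
    matched alias span) in the post-stopword token sequence; ``count``
    is the raw frequency F(n) used by the frequency score.
    """

    part_id: str
    offsets: list[int]

    @property
    def count(self) -> int:
        return len(self.offsets)

    @property
    def first_offset(self) -> int:
        return self.offsets[0]


@dataclass
class ValidationReport:
    root_count: int = 0
    alias_collisions: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_formal_names: list[str] = field(default_factory=list)
    unreachable: list[str] = field(default_factory=list)
    depth_errors: list[str] = field(default_factory=list)
    empty_aliases: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.alias_collisions
            or self.duplicate_formal_names
            or self.unreachable
            or self.depth_errors
            or self.empty_aliases
        )

    def render(self) -> str:
        lines = [f"roots: {self.root_count}"]
        for a, n1, n2 in self.alias_collisions:
            lines.append(f"alias collision: {a!r} -> {n1}, {n2}")
        for name in self.duplicate_formal_names:
            lines.append(f"duplicate formal name: {name!r}")
        for nid in self.unreachable:
            lines.append(f"unreachable node (cycle or missing parent): {nid}")
        for nid in self.depth_errors:
            lines.append(f"depth inconsistency: {nid}")
        for nid in self.empty_aliases:
            lines.append(f"empty alias after cleaning: {nid}")
        if self.ok:
            lines.append("ok")
        return "\n".join(lines)


class Ontology:
    """A validated forest of :class:`BodyPart` nodes with an alias index.

    The alias index maps stemmed token tuples (of every formal name and
    every alias) to node ids; it is the single lookup surface used by
    both exact resolution and in-text scanning.
    """

    def __init__(self, parts: Iterable[BodyPart]):
        self.nodes: dict[str, BodyPart] = {}
        for part in parts:
            if part.id in self.nodes:
                raise OntologyError(f"duplicate node id: {part.id!r}")
            self.nodes[part.id] = part
        self._assign_depths()
        self.roots: list[BodyPart] = [
            p for p in self.nodes.values() if p.parent_id is None
        ]
        self.alias_index: dict[TokenSeq, str] = {}
        self._collisions: list[tuple[str, str, str]] = []
        self._empty_aliases: list[str] = []
        self._build_index()
        self._max_alias_len = max(
            (len(k) for k in self.alias_index), default=0
        )

    def _assign_depths(self) -> None:
        depths: dict[str, int] = {}

        def depth_of(nid: str, trail: tuple[str, ...] = ()) -> int:
            if nid in depths:
                return depths[nid]
            node = self.nodes[nid]
            if node.parent_id is None:
                depths[nid] = 0
            else:
                if nid in trail or node.parent_id not in self.nodes:
                    depths[nid] = -1  # cycle or dangling parent
                else:
                    parent_depth = depth_of(node.parent_id, trail + (nid,))
                    depths[nid] = -1 if parent_depth < 0 else parent_depth + 1
            return depths[nid]

        for nid in list(self.nodes):
            d = depth_of(nid)
            node = self.nodes[nid]
            if node.depth != d:
                self.nodes[nid] = BodyPart(
                    node.id, node.formal_name, node.aliases, node.parent_id, d
                )

    def _build_index(self) -> None:
        for node in self.nodes.values():
            surfaces = (node.formal_name, *node.aliases)
            for surface in surfaces:
                key = tuple(stem_and_clean(surface))
                if not key:
                    self._empty_aliases.append(node.id)
                    continue
                owner = self.alias_index.get(key)
                if owner is not None and owner != node.id:
                    self._collisions.append((" ".join(key), owner, node.id))
                    continue
                self.alias_index[key] = node.id

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[BodyPart]:
        return iter(self.nodes.values())

    def __contains__(self, part_id: str) -> bool:
        return part_id in self.nodes

    def __getitem__(self, part_id: str) -> BodyPart:
        return self.nodes[part_id]

    def depth(self, part_id: str) -> int:
        return self.nodes[part_id].depth

    def to_records(self) -> list[dict]:
        return [
            {
                "id": p.id,
                "formal_name": p.formal_name,
                "aliases": list(p.aliases),
                "parent": p.parent_id,
            }
            for p in self.nodes.values()
        ]


def packaged_thbp_path() -> Path:
    """Path of the THBP ontology file shipped with the package."""
    return Path(_importlib_resources.files("anatomap.data") / "thbp.json")


def load_ontology(path: str | Path | None = None) -> Ontology:
    """Load and validate an ontology file (default: the packaged THBP).

    The file is a JSON array of ``{id, formal_name, aliases, parent}``
    records. Raises :class:`OntologyError` on parse failures, cycles,
    duplicate formal names or alias collisions.
    """
    path = packaged_thbp_path() if path is None else Path(path)
    try:
        records = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise OntologyError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(records, list):
        raise OntologyError(f"{path}: expected a JSON array of node records")

    parts = []
    for i, rec in enumerate(records):
        try:
            parts.append(
                BodyPart(
                    id=str(rec["id"]),
                    formal_name=str(rec["formal_name"]),
                    aliases=tuple(str(a) for a in rec.get("aliases", [])),
                    parent_id=rec.get("parent"),
                )
            )
        except (TypeError, KeyError) as exc:
            raise OntologyError(
                f"{path}: malformed record #{i}: {rec!r}"
            ) from exc

    onto = Ontology(parts)
    report = validate_ontology(onto)
    if not report.ok:
        raise OntologyError(f"{path}: invalid ontology\n{report.render()}")
    return onto


def save_ontology(onto: Ontology, path: str | Path) -> None:
    """Serialize an ontology back to its JSON file format."""
    Path(path).write_text(
        json.dumps(onto.to_records(), indent=2) + "\n", encoding="utf-8"
    )


def resolve_term(onto: Ontology, tokens: Sequence[str]) -> BodyPart | None:
    """Return the node whose formal name or alias equals ``tokens`` exactly.

    ``tokens`` must already be lowercased and stemmed. Absence is a
    valid outcome (returns ``None``), not an error.
    """
    part_id = onto.alias_index.get(tuple(tokens))
    return onto.nodes[part_id] if part_id is not None else None


def find_matches_in_text(
    onto: Ontology, tokens: Sequence[str]
) -> list[OccurrenceList]:
    """Scan a preprocessed token stream for body-part occurrences.

    Left-to-right, longest-match-wins over multi-token aliases, with no
    overlapping matches: "lower extremity" yields one occurrence of the
    lower-extremity node and no embedded "extremity" match. Occurrences
    of different aliases of the same part accumulate into a single
    :class:`OccurrenceList`. Results are in order of first occurrence.
    """
    found: dict[str, OccurrenceList] = {}
    i, n = 0, len(tokens)
    max_len = onto._max_alias_len
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            part_id = onto.alias_index.get(tuple(tokens[i : i + length]))
            if part_id is not None:
                occ = found.get(part_id)
                if occ is None:
                    found[part_id] = OccurrenceList(part_id, [i])
                else:
                    occ.offsets.append(i)
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return list(found.values())


def validate_ontology(onto: Ontology) -> ValidationReport:
    """Report structural violations; the report is empty iff all hold."""
    report = ValidationReport(root_count=len(onto.roots))
    report.alias_collisions = list(onto._collisions)
    report.empty_aliases = list(onto._empty_aliases)

    seen_names: set[str] = set()
    for node in onto:
        if node.formal_name in seen_names:
            report.duplicate_formal_names.append(node.formal_name)
        seen_names.add(node.formal_name)
        if node.depth < 0:
            report.unreachable.append(node.id)
        elif node.parent_id is not None:
            parent = onto.nodes.get(node.parent_id)
            if parent is None or node.depth != parent.depth + 1:
                report.depth_errors.append(node.id)
        elif node.depth != 0:
            report.depth_errors.append(node.id)
    return report
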