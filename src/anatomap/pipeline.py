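"""The mapping cascade: normalize -> direct match -> knowledge-base fallback.

Each mention is normalized, then looked up directly against the
ontology (its core term and every abbreviation expansion); only when
the direct stage finds nothing is the knowledge base consulted: the
mention's explanation is fetched, body parts occurring in it are
collected, and the top-scoring candidate becomes the mapping. Finally
positional modifiers are re-attached to each mapped part's formal name
("legs bilaterally" -> lower extremity -> "bilateral lower extremity").

A mention the baseline (direct string match) can solve never reaches
the knowledge-base branch, so adding the fallback can only extend, not
alter, baseline results.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .kb import KnowledgeSource, fetch_explanation
from .normalize import (
    Mention,
    Resources,
    normalize_mention,
    reattach_positional,
    stem_and_clean,
)
from .ontology import Ontology, find_matches_in_text, resolve_term
from .scoring import ScoringParams, rank_candidates

__all__ = [
    "MappingResult",
    "map_mention",
    "map_corpus",
    "read_mentions_tsv",
    "write_results_tsv",
    "CorpusInputError",
]

logger = logging.getLogger(__name__)

MENTION_COLUMNS = ("doc_id", "mention_id", "start", "end", "surface", "coref_chain_id")
RESULT_COLUMNS = ("mention_id", "stage", "parts", "part_ids", "best_score")


class CorpusInputError(ValueError):
    """Raised for malformed mention input (duplicate ids, bad rows)."""


@dataclass
class MappingResult:
    """Final assignment(s) for one mention.

    ``parts`` holds ``(part_id, final_label)`` pairs — several for
    multi-part abbreviations like HEENT; ``stage`` records which branch
    of the cascade decided (``direct``, ``kb`` or ``unmatched``);
    ``best_score`` is the combined score when the knowledge base decided.
    """

    mention_id: str
    stage: str
    parts: tuple[tuple[str, str], ...]
    best_score: float | None = None

    @property
    def part_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.parts)


def map_mention(
    m: Mention,
    onto: Ontology,
    resources: Resources,
    kb_source: KnowledgeSource | None = None,
    params: ScoringParams | None = None,
    *,
    use_normalization: bool = True,
    use_kb: bool = True,
) -> MappingResult:
    """Run one mention through the cascade.

    ``use_normalization=False`` degrades to the string-matching baseline
    (stem the surface, require an exact ontology hit); ``use_kb=False``
    stops after the direct stage. Both switches exist so ablations of
    the cascade can be evaluated against the full pipeline.
    """
    params = params or ScoringParams()

    if not use_normalization:
        tokens = stem_and_clean(m.surface, resources.stopwords)
        part = resolve_term(onto, tokens)
        if part is None:
            return MappingResult(m.mention_id, "unmatched", ())
        return MappingResult(
            m.mention_id, "direct", ((part.id, part.formal_name),)
        )

    nm = normalize_mention(m, resources, onto)

    hits = []
    core_part = resolve_term(onto, nm.core_tokens) if nm.core_tokens else None
    if core_part is not None:
        hits.append(core_part)
        if nm.expansions:
            logger.debug(
                "mention %s: direct core resolution wins over expansions",
                m.mention_id,
            )
    else:
        seen: set[str] = set()
        for expansion in nm.expansions:
            part = resolve_term(onto, expansion)
            if part is not None and part.id not in seen:
                seen.add(part.id)
                hits.append(part)

    if hits:
        parts = tuple(
            (p.id, reattach_positional(nm.positionals, p.formal_name))
            for p in hits
        )
        return MappingResult(m.mention_id, "direct", parts)

    if use_kb and kb_source is not None and nm.core_tokens:
        explanation = None
        for query in (" ".join(nm.core_tokens), m.surface.lower()):
            explanation = fetch_explanation(kb_source, query)
            if explanation is not None:
                break
        if explanation is not None:
            occs = find_matches_in_text(onto, explanation.tokens)
            ranked = rank_candidates(occs, onto, params)
            if ranked:
                best = ranked[0]
                part = onto[best.part_id]
                label = reattach_positional(nm.positionals, part.formal_name)
                return MappingResult(
                    m.mention_id, "kb", ((part.id, label),), best.score
                )

    return MappingResult(m.mention_id, "unmatched", ())


def map_corpus(
    mentions: "Iterable[Mention] | str | Path",
    onto: Ontology,
    resources: Resources,
    kb_source: KnowledgeSource | None = None,
    params: ScoringParams | None = None,
    *,
    use_normalization: bool = True,
    use_kb: bool = True,
) -> list[MappingResult]:
    """Map every mention of a corpus, in input order.

    Accepts an iterable of :class:`Mention` or a path to a mention TSV.
    Knowledge-base fetches are cached per source, so repeated terms cost
    one lookup. Logs per-stage counts at INFO.
    """
    if isinstance(mentions, (str, Path)):
        mentions = read_mentions_tsv(mentions)

    results: list[MappingResult] = []
    seen_ids: set[str] = set()
    for row, m in enumerate(mentions, start=1):
        if m.mention_id in seen_ids:
            raise CorpusInputError(
                f"duplicate mention_id {m.mention_id!r} at row {row}"
            )
        seen_ids.add(m.mention_id)
        results.append(
            map_mention(
                m,
                onto,
                resources,
                kb_source,
                params,
                use_normalization=use_normalization,
                use_kb=use_kb,
            )
        )

    counts = Counter(r.stage for r in results)
    logger.info(
        "mapped %d mentions: %s",
        len(results),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none",
    )
    return results


def read_mentions_tsv(path: str | Path) -> list[Mention]:
    """Read a mention TSV (doc_id, mention_id, start, end, surface[, coref])."""
    out: list[Mention] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row_no, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                out.append(
                    Mention(
                        doc_id=row["doc_id"],
                        mention_id=row["mention_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        surface=row["surface"],
                        coref_chain_id=row.get("coref_chain_id") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise CorpusInputError(
                    f"{path}: bad mention at line {row_no}: {exc}"
                ) from exc
    return out


def write_results_tsv(results: Sequence[MappingResult], path: str | Path) -> None:
    """Write results (mention_id, stage, parts, part_ids, best_score)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.mention_id,
                    r.stage,
                    ";".join(label for _, label in r.parts),
                    ";".join(r.part_ids),
                    "" if r.best_score is None else f"{r.best_score:.6f}",
                ]
            )
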