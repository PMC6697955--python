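"""Brute-force reference scorer, independent of the scoring module.

Re-derives the distance value, frequency, cosine sub-score and combined
score directly from raw offset lists, with its own arithmetic and its
own tie handling — no code is shared with :mod:`anatomap.scoring`. It
exists so the production ranker can always be cross-checked against a
second, straight-line implementation, and so the synthetic-data
generator can verify at generation time that its planted winner really
is the argmax.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

__all__ = ["brute_force_best", "brute_force_scores"]


def brute_force_scores(
    occurrences: Mapping[str, Sequence[int]],
    a: float = 15.0,
    b: float = 1.0,
    first_multiplier: float = 2.5,
    distance_mode: str = "mean_offset",
) -> dict[str, float]:
    """Combined score per candidate, recomputed from raw offsets."""
    if not occurrences:
        return {}

    items = list(occurrences.items())

    firsts = {pid: min(offs) for pid, offs in items}
    first_part = min(items, key=lambda kv: min(kv[1]))[0]

    order = sorted(firsts, key=lambda pid: firsts[pid])
    rank_of = {pid: i + 1 for i, pid in enumerate(order)}

    dist: dict[str, float] = {}
    for pid, offs in items:
        if distance_mode == "mean_offset":
            dist[pid] = sum(offs) / len(offs)
        elif distance_mode == "first_offset":
            dist[pid] = float(min(offs))
        elif distance_mode == "matched_rank":
            dist[pid] = float(rank_of[pid])
        else:
            raise ValueError(distance_mode)
    max_d = max(dist.values())

    scores: dict[str, float] = {}
    for pid, offs in items:
        if max_d == 0:
            fd = 0.0
        elif max_d == 1:
            fd = 1.0
        else:
            fd = math.cos(dist[pid] * math.pi / (2 * max_d))
        freq = len(offs)
        ff = first_multiplier * freq if pid == first_part else float(freq)
        scores[pid] = a * fd + b * ff
    return scores


def brute_force_best(
    occurrences: Mapping[str, Sequence[int]],
    depths: Mapping[str, int] | None = None,
    a: float = 15.0,
    b: float = 1.0,
    first_multiplier: float = 2.5,
    distance_mode: str = "mean_offset",
    tie_break: str = "deeper_node",
    tol: float = 1e-9,
) -> str | None:
    """The argmax candidate, with explicit enumeration of score ties."""
    scores = brute_force_scores(
        occurrences, a, b, first_multiplier, distance_mode
    )
    if not scores:
        return None
    top = max(scores.values())
    tied = [pid for pid, s in scores.items() if top - s <= tol]
    if len(tied) == 1:
        return tied[0]
    firsts = {pid: min(occurrences[pid]) for pid in tied}
    if tie_break == "deeper_node" and depths is not None:
        deepest = max(depths.get(pid, 0) for pid in tied)
        tied = [pid for pid in tied if depths.get(pid, 0) == deepest]
        if len(tied) == 1:
            return tied[0]
    if tie_break in ("deeper_node", "earliest_occurrence"):
        earliest = min(firsts[pid] for pid in tied)
        tied = [pid for pid in tied if firsts[pid] == earliest]
    return sorted(tied)[0]
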