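"""Distance/frequency scoring of body-part candidates in an explanation.

Given the body parts found in an explanation text (with their token
offsets), each candidate n receives

    Score(n) = a * f(D(n)) + b * f(F(n))

where the distance sub-score maps the candidate's offset D(n) into
[0, 1] with a quarter-period cosine,

    f(D) = cos(D * (pi/2) / maxD)   if maxD > 1
           1                        if maxD = 1
           0                        if maxD = 0

(maxD is the largest D among the candidates, so the last-appearing
candidate scores 0 and an onset occurrence scores 1), and the frequency
sub-score is the raw occurrence count F(n), boosted by a constant
multiplier (default 2.5) for the single candidate that appears first in
the text. Defaults a = 15, b = 1. The argmax candidate is the mapping
result; ties (within 1e-9) break to the deeper ontology node, matching
the convention that results live on the lowest layer of the tree.

D(n) is configurable: the mean of the candidate's offsets (default,
matching "average distance from the onset"), its first offset, or the
1-based rank of its first occurrence among candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cmp_to_key
from typing import TYPE_CHECKING, Sequence

from .ontology import OccurrenceList

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

__all__ = [
    "ScoringParams",
    "CandidateScore",
    "distance_value",
    "distance_score",
    "frequency_score",
    "combined_score",
    "rank_candidates",
]

_TIE_TOL = 1e-9

DISTANCE_MODES = ("mean_offset", "first_offset", "matched_rank")
TIE_BREAKS = ("deeper_node", "earliest_occurrence", "lexicographic")
ALGORITHMS = ("distance", "frequency", "combined")


@dataclass(frozen=True)
class ScoringParams:
    """Coefficients and policies of the combined score.

    ``algorithm`` selects distance-only (b = 0), frequency-only (a = 0)
    or the combined score; the coefficient actually used is derived in
    :meth:`effective`.
    """

    a: float = 15.0
    b: float = 1.0
    first_multiplier: float = 2.5
    distance_mode: str = "mean_offset"
    tie_break: str = "deeper_node"
    algorithm: str = "combined"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.first_multiplier <= 0:
            raise ValueError("coefficients must be positive")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def effective(self) -> "ScoringParams":
        if self.algorithm == "distance":
            return replace(self, b=0.0, algorithm="combined")
        if self.algorithm == "frequency":
            return replace(self, a=0.0, algorithm="combined")
        return self

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScoringParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in cfg.items() if k in known})


@dataclass
class CandidateScore:
    """One candidate with its distance/frequency components and score."""

    part_id: str
    D: float
    F: int
    is_first: bool
    f_D: float
    f_F: float
    score: float
    first_offset: int


def distance_value(
    occ: OccurrenceList, mode: str = "mean_offset", rank: int | None = None
) -> float:
    """The candidate's D(n) under the chosen distance convention."""
    if occ.count < 1:
        raise ValueError("occurrence list must be non-empty")
    if mode == "mean_offset":
        return sum(occ.offsets) / occ.count
    if mode == "first_offset":
        return float(occ.first_offset)
    if mode == "matched_rank":
        if rank is None:
            raise ValueError("matched_rank mode requires the caller's rank")
        return float(rank)
    raise ValueError(f"unknown distance_mode {mode!r}")


def distance_score(D: float, maxD: float) -> float:
    """Cosine-normalized distance sub-score in [0, 1]."""
    if D < 0 or D > maxD:
        raise ValueError(f"need 0 <= D <= maxD, got D={D}, maxD={maxD}")
    if maxD == 0:
        return 0.0
    if maxD == 1:
        return 1.0
    return math.cos(D * (math.pi / 2) / maxD)


def frequency_score(
    F: float, is_first: bool, first_multiplier: float = 2.5
) -> float:
    """Raw frequency, boosted for the first-appearing candidate."""
    if F < 0:
        raise ValueError("frequency must be non-negative")
    return first_multiplier * F if is_first else float(F)


def combined_score(f_D: float, f_F: float, params: ScoringParams) -> float:
    """Score(n) = a * f_D + b * f_F."""
    return params.a * f_D + params.b * f_F


def _tie_cmp(params: ScoringParams, onto: "Ontology | None"):
    def compare(x: CandidateScore, y: CandidateScore) -> int:
        if abs(x.score - y.score) > _TIE_TOL:
            return -1 if x.score > y.score else 1
        if params.tie_break == "deeper_node" and onto is not None:
            dx, dy = onto.depth(x.part_id), onto.depth(y.part_id)
            if dx != dy:
                return -1 if dx > dy else 1
        if params.tie_break in ("deeper_node", "earliest_occurrence"):
            if x.first_offset != y.first_offset:
                return -1 if x.first_offset < y.first_offset else 1
        return -1 if x.part_id < y.part_id else (1 if x.part_id > y.part_id else 0)

    return compare


def rank_candidates(
    occs: Sequence[OccurrenceList],
    onto: "Ontology | None" = None,
    params: ScoringParams | None = None,
) -> list[CandidateScore]:
    """Score and order all candidates found in one explanation.

    The head of the returned list is the selected mapping. Empty input
    yields an empty list (the caller treats that as unmatched).
    """
    if not occs:
        return []
    params = (params or ScoringParams()).effective()

    by_first = sorted(range(len(occs)), key=lambda i: (occs[i].first_offset, i))
    first_index = by_first[0]
    ranks = {idx: r + 1 for r, idx in enumerate(by_first)}

    D_values = [
        distance_value(occ, params.distance_mode, rank=ranks[i])
        for i, occ in enumerate(occs)
    ]
    maxD = max(D_values)

    scored = []
    for i, occ in enumerate(occs):
        is_first = i == first_index
        f_D = distance_score(D_values[i], maxD)
        f_F = frequency_score(occ.count, is_first, params.first_multiplier)
        scored.append(
            CandidateScore(
                part_id=occ.part_id,
                D=D_values[i],
                F=occ.count,
                is_first=is_first,
                f_D=f_D,
                f_F=f_F,
                score=combined_score(f_D, f_F, params),
                first_offset=occ.first_offset,
            )
        )
    scored.sort(key=cmp_to_key(_tie_cmp(params, onto)))
    return scored
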