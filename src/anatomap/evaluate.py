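"""Mention-level precision/recall/F1 against gold mappings.

Counts are micro-averaged over (mention_id, part_id) pairs so that
multi-part abbreviations (HEENT -> five parts) contribute one pair per
part: a predicted pair also in gold is a true positive, a predicted
pair absent from gold a false positive, a gold pair never predicted a
false negative. Unmatched predictions assert nothing and contribute no
pairs. Matching is by part id by default; ``strict_labels`` compares
full positional-prefixed labels instead.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .pipeline import MappingResult

__all__ = ["EvalReport", "evaluate", "read_gold_tsv", "EvalInputError"]


class EvalInputError(ValueError):
    """Prediction/gold files that cannot be compared."""


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision_pct": round(100 * self.precision, 2),
            "recall_pct": round(100 * self.recall, 2),
            "f1_pct": round(100 * self.f1, 2),
        }

    def render(self) -> str:
        d = self.as_dict()
        return (
            f"P = {d['precision_pct']:.2f}%  R = {d['recall_pct']:.2f}%  "
            f"F1 = {d['f1_pct']:.2f}%  (tp={self.tp} fp={self.fp} fn={self.fn})"
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=2) + "\n", encoding="utf-8"
        )


PredictionsLike = "Sequence[MappingResult] | Mapping[str, Sequence[str]] | str | Path"
GoldLike = "Mapping[str, Sequence[str]] | str | Path"


def _pairs_from_predictions(predictions, strict_labels: bool) -> tuple[set, set]:
    """Return (pair set, mention-id set) from any accepted prediction form."""
    pairs: set[tuple[str, str]] = set()
    ids: set[str] = set()
    if isinstance(predictions, (str, Path)):
        predictions = _read_result_tsv(predictions, strict_labels)
    if isinstance(predictions, Mapping):
        for mid, parts in predictions.items():
            ids.add(mid)
            pairs.update((mid, p) for p in parts)
        return pairs, ids
    for r in predictions:
        ids.add(r.mention_id)
        if strict_labels:
            pairs.update((r.mention_id, label) for _, label in r.parts)
        else:
            pairs.update((r.mention_id, pid) for pid in r.part_ids)
    return pairs, ids


def _read_result_tsv(path, strict_labels: bool) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    column = "parts" if strict_labels else "part_ids"
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            values = [p for p in row.get(column, "").split(";") if p]
            out[row["mention_id"]] = values
    return out


def read_gold_tsv(path: str | Path) -> dict[str, list[str]]:
    """Gold TSV columns: mention_id, part_ids (semicolon-separated)."""
    gold: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mid = row["mention_id"]
            if mid in gold:
                raise EvalInputError(f"{path}: duplicate gold mention_id {mid!r}")
            gold[mid] = [p for p in row["part_ids"].split(";") if p]
    return gold


def evaluate(
    predictions,
    gold,
    strict_labels: bool = False,
) -> EvalReport:
    """Micro-averaged P/R/F1 over (mention, part) pairs.

    ``predictions`` may be mapping results, a ``{mention_id: parts}``
    mapping, or a result TSV path; ``gold`` a mapping or gold TSV path.
    Every predicted mention_id must exist in gold.
    """
    if isinstance(gold, (str, Path)):
        gold = read_gold_tsv(gold)
    pred_pairs, pred_ids = _pairs_from_predictions(predictions, strict_labels)

    unknown = pred_ids - set(gold)
    if unknown:
        raise EvalInputError(
            f"predictions reference mention_ids absent from gold: "
            f"{sorted(unknown)[:5]}"
        )

    gold_pairs = {
        (mid, p) for mid, parts in gold.items() for p in parts
    }
    tp = len(pred_pairs & gold_pairs)
    fp = len(pred_pairs - gold_pairs)
    fn = len(gold_pairs - pred_pairs)
    return EvalReport(tp=tp, fp=fp, fn=fn)
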