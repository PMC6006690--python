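"""Accuracy scoring of gap-filling predictions, and the packaged reference
data from the published *Bifidobacterium longum* gap-filling comparison.

A predicted reaction set is scored against a reference (e.g. manually
curated) set by exact id matching: shared ids are true positives, ids only
in the prediction are false positives, ids only in the reference are false
negatives, and recall/precision follow.  Near-equivalent reaction pairs —
distinct database ids describing essentially the same transformation — are
deliberately *not* merged; they count as fp/fn, matching the scoring
convention of the study this package replays.  An informational near-miss
report is available separately.

Three reference tables ship as package data:

* the 53 biomass metabolites of the B. longum model, 15 of which were
  producible before gap filling;
* the automated (12 reactions, 2 of them excess) and manual (13 reactions)
  gap-filling solutions;
* the 28 reactions whose directionality was manually curated during model
  development.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

from .netcore import ReactionSpec

__all__ = [
    "EvaluationResult",
    "Table1Row",
    "Table2Entry",
    "Table4Row",
    "ReferenceTables",
    "evaluate_solution",
    "load_fixtures",
    "as_percent",
    "near_misses",
]


def as_percent(fraction: float) -> float:
    """A fraction as a percentage truncated (not rounded) to one decimal
    place — the presentation convention of the reference study, whose
    printed 66.6% corresponds to 8/12."""
    return math.floor(fraction * 1000 + 1e-9) / 10


@dataclass(frozen=True)
class EvaluationResult:
    """Set-level comparison of a predicted against a reference reaction set."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    shared: frozenset
    predicted_only: frozenset
    reference_only: frozenset

    @property
    def recall_percent(self) -> float:
        return as_percent(self.recall)

    @property
    def precision_percent(self) -> float:
        return as_percent(self.precision)


def evaluate_solution(predicted: Iterable[str], reference: Iterable[str]) -> EvaluationResult:
    """Score ``predicted`` against ``reference`` by exact id matching.

    Inputs are treated as sets (ordering and duplication are irrelevant);
    both must be nonempty, since recall and precision are undefined on empty
    denominators.
    """
    predicted = frozenset(predicted)
    reference = frozenset(reference)
    if not predicted:
        raise ValueError("predicted reaction set is empty")
    if not reference:
        raise ValueError("reference reaction set is empty")
    shared = predicted & reference
    tp = len(shared)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    return EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        recall=tp / (tp + fn),
        precision=tp / (tp + fp),
        shared=shared,
        predicted_only=predicted - reference,
        reference_only=reference - predicted,
    )


def near_misses(
    predicted: Mapping[str, ReactionSpec], reference: Mapping[str, ReactionSpec]
) -> list:
    """Informational report of near-equivalent (predicted, reference) pairs.

    Pairs a prediction-only reaction with a reference-only reaction when
    their stoichiometries are identical — distinct ids for the same net
    transformation.  Purely informational: near misses never change
    tp/fp/fn.
    """
    p_only = {k: v for k, v in predicted.items() if k not in reference}
    r_only = {k: v for k, v in reference.items() if k not in predicted}
    pairs = []
    for pid, prxn in sorted(p_only.items()):
        for rid, rrxn in sorted(r_only.items()):
            if dict(prxn.stoichiometry) == dict(rrxn.stoichiometry):
                pairs.append((pid, rid))
    return pairs


class Table1Row(NamedTuple):
    name: str
    biocyc_id: str
    producible_pre_gapfill: bool


class Table2Entry(NamedTuple):
    biocyc_id: str
    automated: bool  # in the automated gap filler's 12-reaction solution
    manual: bool  # in the 13-reaction manually curated solution
    starred: bool  # excess automated prediction, not needed for growth


class Table4Row(NamedTuple):
    biocyc_id: str
    metabolic_goal: str
    curated_direction: str


@dataclass(frozen=True)
class ReferenceTables:
    """The published reference tables as typed rows."""

    table1: tuple
    table2: tuple
    table4: tuple

    @property
    def automated_set(self) -> frozenset:
        return frozenset(e.biocyc_id for e in self.table2 if e.automated)

    @property
    def manual_set(self) -> frozenset:
        return frozenset(e.biocyc_id for e in self.table2 if e.manual)

    @property
    def starred_set(self) -> frozenset:
        return frozenset(e.biocyc_id for e in self.table2 if e.starred)

    @property
    def minimum_automated_set(self) -> frozenset:
        """The automated solution with its excess (starred) reactions removed —
        the minimum reaction set that enables growth of the model."""
        return self.automated_set - self.starred_set

    @property
    def producible_pre_gapfill(self) -> frozenset:
        return frozenset(
            r.biocyc_id for r in self.table1 if r.producible_pre_gapfill
        )


def _read_rows(filename: str) -> list:
    ref = resources.files("gapfillkit.data").joinpath(filename)
    with ref.open("rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = [row + [""] * (len(header) - len(row)) for row in reader if row]
    return rows


_COUNTS = {"table1": 53, "table2_automated": 12, "table2_manual": 13, "table4": 28}


def load_fixtures() -> ReferenceTables:
    """Load the packaged reference tables, verifying their integrity counts."""
    t1 = tuple(
        Table1Row(name, bid, flag.strip().upper() == "X")
        for name, bid, flag in _read_rows("table1_biomass_metabolites.tsv")
    )
    t2 = []
    for bid, added_by in _read_rows("table2_gapfill_solutions.tsv"):
        marks = {m.strip() for m in added_by.split(",")}
        t2.append(Table2Entry(bid, "A" in marks, "M" in marks, "*" in marks))
    t2 = tuple(t2)
    t4 = tuple(
        Table4Row(bid, goal, direction)
        for bid, goal, direction in _read_rows("table4_direction_curation.tsv")
    )
    fixtures = ReferenceTables(t1, t2, t4)
    checks = {
        "table1": len(t1),
        "table2_automated": len(fixtures.automated_set),
        "table2_manual": len(fixtures.manual_set),
        "table4": len(t4),
    }
    bad = {k: (v, _COUNTS[k]) for k, v in checks.items() if v != _COUNTS[k]}
    if bad:
        raise RuntimeError(f"packaged fixture integrity check failed: {bad}")
    return fixtures
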