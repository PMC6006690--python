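"""Post-hoc quality control of gap-filling solutions.

MILP solvers work at finite numerical tolerances, and a returned selection
can disagree with the flux values that accompany it: a candidate declared
unselected (``s_r = 0``) may carry flux at or above the active lower bound
``B_l``, or a selected one may exceed ``B_u``.  :func:`audit_solution`
detects exactly these indicator-constraint violations from the raw MILP
variable values.

Independently of numerics, a returned solution may simply be larger than
necessary.  :func:`verify_minimality` greedily removes reactions (most
expensive first) while an independent FBA growth check still passes,
yielding a *minimal* set — one where every member is essential.  Note that a
minimal set is not necessarily the *minimum-cost* set; the exact optimum on
small candidate databases is available from
:func:`brute_force_min_gapfill`, which enumerates subsets in increasing cost
order and serves as the testing oracle for the MILP gap filler.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional

from .fba import grows
from .gapfill import GapFillConfig, MILPState, candidate_cost
from .netcore import MetabolicModel, ReactionSpec, augmented

__all__ = [
    "Violation",
    "ViolationReport",
    "audit_solution",
    "verify_minimality",
    "brute_force_min_gapfill",
    "BRUTE_FORCE_GUARD",
]

#: Largest candidate database brute_force_min_gapfill will enumerate.
BRUTE_FORCE_GUARD = 20


class Violation(NamedTuple):
    reaction_id: str
    s_value: float
    f_value: float
    bound: str  # "lower" (s=0 but |f| >= B_l) or "upper" (s=1 but |f| > B_u)


@dataclass(frozen=True)
class ViolationReport:
    """Indicator-constraint audit outcome; ``clean`` iff no violations."""

    violations: tuple
    clean: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "violations", tuple(self.violations))
        if self.clean != (len(self.violations) == 0):
            raise ValueError("clean flag inconsistent with violation list")


def audit_solution(milp_state: MILPState, config: GapFillConfig) -> ViolationReport:
    """Check every candidate's ``B_l s_r <= f_r <= B_u s_r`` coupling.

    A violation is recorded iff the (rounded) selection is 0 while the flux
    magnitude reaches the active lower bound ``B_l``, or the selection is 1
    while the flux exceeds ``B_u`` beyond the audit tolerance.  Pure function
    of its inputs.
    """
    missing = set(milp_state.s) ^ set(milp_state.f)
    if missing:
        raise ValueError(
            f"candidates with missing s or f entries: {sorted(missing)}"
        )
    violations = []
    for rid in sorted(milp_state.s):
        s = milp_state.s[rid]
        f = abs(milp_state.f[rid])
        selected = s >= 0.5
        if not selected and f >= config.B_l:
            violations.append(Violation(rid, s, milp_state.f[rid], "lower"))
        elif selected and f > config.B_u + config.audit_tol:
            violations.append(Violation(rid, s, milp_state.f[rid], "upper"))
    return ViolationReport(tuple(violations), not violations)


def _cost_lookup(
    database: Iterable[ReactionSpec], config: GapFillConfig
) -> dict:
    return {r.id: (candidate_cost(r, config), r) for r in database}


def verify_minimality(
    model: MetabolicModel,
    solution: Iterable[str],
    database: Iterable[ReactionSpec],
    config: GapFillConfig = GapFillConfig(),
) -> tuple:
    """Greedy reduction of a gap-filling solution to a minimal set.

    Attempts to remove each solution reaction in descending cost order (ties
    broken by ascending reaction id); a reaction is permanently removed when
    the model still grows without it (checked by FBA at the configured
    biomass threshold).  Returns ``(minimal_set, removed)``.  Every member of
    the returned set is essential — its sole removal stops growth — but the
    set is minimal, not necessarily minimum-cost.
    """
    lookup = _cost_lookup(database, config)
    solution = set(solution)
    unknown = solution - lookup.keys()
    if unknown:
        raise ValueError(f"solution reactions not in database: {sorted(unknown)}")
    current = set(solution)

    def _model_with(ids: set) -> MetabolicModel:
        return augmented(model, [lookup[r][1] for r in sorted(ids)])

    if not grows(_model_with(current), config.biomass_threshold):
        raise ValueError("solution does not enable growth")
    order = sorted(current, key=lambda r: (-lookup[r][0], r))
    removed = set()
    for rid in order:
        trial = current - {rid}
        if grows(_model_with(trial), config.biomass_threshold):
            current = trial
            removed.add(rid)
    return frozenset(current), frozenset(removed)


def brute_force_min_gapfill(
    model: MetabolicModel,
    database: Iterable[ReactionSpec],
    config: GapFillConfig = GapFillConfig(),
    max_size: Optional[int] = None,
) -> Optional[tuple]:
    """Exact minimum-cost completion by subset enumeration.

    Candidate subsets (after the polymerization filter) are tried in
    increasing (cost, size, lexicographic) order; the first subset whose
    addition makes the model grow is the optimum by construction.  Returns
    ``(best_set, best_cost)`` or None when no subset of size <= ``max_size``
    enables growth.  Refuses databases larger than ``BRUTE_FORCE_GUARD``.
    Reversal of existing reactions is not enumerated; compare against
    :func:`gapfillkit.gapfill.gapfill` with ``allow_reversal=False``.
    """
    db = sorted(database, key=lambda r: r.id)
    if config.exclude_polymerization:
        db = [r for r in db if not r.is_polymerization]
    if len(db) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"{len(db)} candidates exceed the enumeration guard "
            f"({BRUTE_FORCE_GUARD}); use the MILP gap filler"
        )
    if max_size is None:
        max_size = len(db)
    subsets = []
    for k in range(0, max_size + 1):
        for combo in itertools.combinations(db, k):
            cost = sum(candidate_cost(r, config) for r in combo)
            subsets.append((cost, k, tuple(r.id for r in combo), combo))
    subsets.sort(key=lambda t: (t[0], t[1], t[2]))
    for cost, _, ids, combo in subsets:
        candidate_model = augmented(model, combo)
        if grows(candidate_model, config.biomass_threshold):
            return frozenset(ids), float(cost)
    return None
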