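"""Minimum-cost MILP gap filling.

Given a model that fails to grow and a database of candidate reactions, the
gap filler chooses a cheapest set of candidates to add — and, optionally,
existing irreversible reactions to reverse — such that the completed network
attains a biomass flux above the growth threshold.

Each candidate ``r`` gets a Boolean selection variable ``s_r`` coupled to its
flux ``f_r`` by the indicator constraints

    B_l * s_r  <=  f_r  <=  B_u * s_r

so a deselected candidate can carry no flux and a selected one must carry at
least the minimum active flux ``B_l``.  Reversing an existing irreversible
reaction is modeled the same way: a Boolean per reaction gates an extra flux
column running in the forbidden direction.  The objective minimizes the sum
of action costs, with the strict ordering

    cost(reverse existing) < cost(insert in-taxon) < cost(insert out-of-taxon)

so taxonomically plausible completions are preferred.  The MILP is solved
with HiGHS; every solution is re-validated by an independent LP growth check
and audited for indicator-constraint violations (see :mod:`gapfillkit.verify`)
— MILP solvers can return selections whose flux values violate the declared
couplings, and such solutions must be flagged rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import GROWTH_THRESHOLD, FluxState, SolverError, grows, producible_biomass_subset, solve_fba
from .netcore import (
    BIOMASS_COLUMN,
    Direction,
    MetabolicModel,
    ReactionSpec,
    augmented,
    build_matrix,
)

__all__ = [
    "GapFillConfig",
    "MILPState",
    "GapFillSolution",
    "gapfill",
    "enumerate_equal_cost_solutions",
    "candidate_cost",
]


@dataclass(frozen=True)
class GapFillConfig:
    """Tunable parameters of the gap filler.

    ``B_l``/``B_u`` bound the flux of any reaction considered active (flux
    units); ``biomass_threshold`` is the minimum biomass flux counted as
    growth.  The three weights order the costs of the possible actions; only
    the strict ordering ``w_reverse < w_insert_in_taxon < w_insert_out_taxon``
    is meaningful, the defaults 1 < 2 < 4 are a convention.
    Polymerization/depolymerization reactions are excluded from candidacy by
    default because their generic polymer stoichiometry is not mass-balanced
    at the instance level.
    """

    B_l: float = 1e-3
    B_u: float = 3000.0
    biomass_threshold: float = 1e-3
    w_reverse: float = 1.0
    w_insert_in_taxon: float = 2.0
    w_insert_out_taxon: float = 4.0
    exclude_polymerization: bool = True
    allow_reversal: bool = True
    seed: int = 0
    randomize_ties: bool = False
    time_limit: float = 60.0
    mip_gap: float = 1e-6
    #: MIP integrality tolerance.  Must satisfy B_u * int_tol << B_l: a binary
    #: accepted at integrality-tolerance distance from 0 still admits flux up
    #: to B_u * int_tol through the indicator coupling, which at looser
    #: tolerances silently turns deselected candidates into active ones.
    int_tol: float = 1e-9
    audit_tol: float = 1e-6
    #: additive slack turning the strict growth inequality into ``>=``
    strict_eps: float = 1e-9
    #: magnitude of the deterministic tie-breaking cost perturbation
    tie_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.B_l < self.B_u):
            raise ValueError("require 0 < B_l < B_u")
        if not (0 < self.w_reverse < self.w_insert_in_taxon < self.w_insert_out_taxon):
            raise ValueError(
                "require 0 < w_reverse < w_insert_in_taxon < w_insert_out_taxon"
            )
        if self.biomass_threshold <= 0:
            raise ValueError("biomass_threshold must be positive")


def candidate_cost(rxn: ReactionSpec, config: GapFillConfig) -> float:
    """Insertion cost of a database candidate under the configured weights."""
    return (
        config.w_insert_in_taxon
        if rxn.in_taxonomic_range
        else config.w_insert_out_taxon
    )


@dataclass(frozen=True)
class MILPState:
    """Raw MILP variable values, kept for post-hoc auditing.

    ``s`` maps candidate id to its selection value, ``f`` to its (split-column
    summed) flux magnitude; ``rev`` maps reversal-eligible reaction ids to
    their reversal value.  The audit module checks the declared coupling
    ``B_l s_r <= f_r <= B_u s_r`` against these values — violations are its
    subject, never silently accepted here.
    """

    s: Mapping[str, float]
    f: Mapping[str, float]
    rev: Mapping[str, float]
    solver_status: str
    objective: float


@dataclass(frozen=True)
class GapFillSolution:
    """One gap-filling outcome.

    ``added``/``reversed`` name the chosen actions, ``total_cost`` their
    weight sum recomputed from the configured (unperturbed) weights,
    ``flux_state`` the independent-LP flux distribution of the completed
    model, and ``audit`` the indicator-constraint violation report.
    ``unproducible`` lists the biomass metabolites no database completion can
    reach (populated only for infeasible problems).
    """

    added: frozenset
    reversed: frozenset
    total_cost: float
    flux_state: Optional[FluxState]
    status: str  # optimal | feasible | infeasible | timeout
    audit: object = None
    milp_state: Optional[MILPState] = None
    unproducible: frozenset = frozenset()


def _filtered_candidates(
    model: MetabolicModel, database: Iterable[ReactionSpec], config: GapFillConfig
) -> list:
    db = list(database)
    ids = [r.id for r in db]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reaction ids in candidate database")
    clash = set(ids) & model.reactions.keys()
    if clash:
        raise ValueError(f"database ids not disjoint from model: {sorted(clash)}")
    if config.exclude_polymerization:
        db = [r for r in db if not r.is_polymerization]
    return sorted(db, key=lambda r: r.id)


def _tie_epsilons(n: int, config: GapFillConfig) -> np.ndarray:
    """Tiny per-binary cost perturbations: strictly increasing with rank, so
    equal-cost optima resolve deterministically (lexicographically smallest
    id set preferred).  With ``randomize_ties`` the rank order is shuffled
    from the seed, emulating a solver that picks among ties at random."""
    if n == 0:
        return np.zeros(0)
    eps = config.tie_eps * (np.arange(1, n + 1) / n)
    if config.randomize_ties:
        rng = np.random.Generator(np.random.Philox(config.seed))
        eps = rng.permutation(eps)
    return eps


class _MilpProblem:
    """Assembled MILP over the combined model + candidate network."""

    def __init__(
        self,
        model: MetabolicModel,
        candidates: Sequence[ReactionSpec],
        config: GapFillConfig,
    ) -> None:
        self.model = model
        self.candidates = list(candidates)
        self.config = config
        combined = augmented(model, self.candidates)
        smat = build_matrix(combined, flux_bound=config.B_u)
        self.smat = smat
        n_flux = len(smat.columns)

        # columns of each candidate (1 or 2 after direction splitting)
        self.cand_cols = {
            c.id: [
                j
                for j, col in enumerate(smat.columns)
                if col.reaction_id == c.id
            ]
            for c in self.candidates
        }
        # reversal columns: one extra flux variable per irreversible model reaction,
        # running opposite to its written direction
        self.rev_ids: list = []
        rev_entries: list = []
        if config.allow_reversal:
            for rid, rxn in model.reactions.items():
                if rxn.direction is Direction.REVERSIBLE:
                    continue
                sign = -1.0 if rxn.direction is Direction.L2R else 1.0
                self.rev_ids.append(rid)
                rev_entries.append(
                    {m: sign * c for m, c in rxn.stoichiometry.items()}
                )
        n_rev = len(self.rev_ids)
        n_cand = len(self.candidates)

        # variable layout: [flux columns | reversal flux | s binaries | rev binaries]
        self.n_flux = n_flux
        self.off_revflux = n_flux
        self.off_s = n_flux + n_rev
        self.off_rev = self.off_s + n_cand
        n_var = self.off_rev + n_rev

        lb = np.zeros(n_var)
        ub = np.empty(n_var)
        flb, fub = smat.column_bounds()
        ub[:n_flux] = fub
        lb[:n_flux] = flb
        ub[self.off_revflux : self.off_s] = config.B_u
        ub[self.off_s :] = 1.0
        # growth demanded outright: strict '>' expressed as '>= threshold + eps'
        dm = smat.column_index[BIOMASS_COLUMN]
        lb[dm] = config.biomass_threshold + config.strict_eps
        self.bounds = Bounds(lb, ub)

        integrality = np.zeros(n_var)
        integrality[self.off_s :] = 1
        self.integrality = integrality

        # steady state over all flux-carrying variables
        rows, cols, vals = [], [], []
        coo = smat.matrix.tocoo()
        rows.extend(coo.row)
        cols.extend(coo.col)
        vals.extend(coo.data)
        ridx = smat.row_index
        for k, entries in enumerate(rev_entries):
            for m, c in entries.items():
                rows.append(ridx[m])
                cols.append(self.off_revflux + k)
                vals.append(c)
        A_eq = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(smat.rows), n_var)
        )
        constraints = [LinearConstraint(A_eq.tocsr(), 0.0, 0.0)]

        # indicator couplings  B_l * b <= f <= B_u * b  for candidates and reversals
        c_rows, c_cols, c_vals, c_lo, c_hi = [], [], [], [], []
        row = 0

        def _couple(flux_cols, bin_col):
            nonlocal row
            for j in flux_cols:  # f - B_u b <= 0
                c_rows.append(row), c_cols.append(j), c_vals.append(1.0)
            c_rows.append(row), c_cols.append(bin_col), c_vals.append(-config.B_u)
            c_lo.append(-np.inf), c_hi.append(0.0)
            row += 1
            for j in flux_cols:  # f - B_l b >= 0
                c_rows.append(row), c_cols.append(j), c_vals.append(1.0)
            c_rows.append(row), c_cols.append(bin_col), c_vals.append(-config.B_l)
            c_lo.append(0.0), c_hi.append(np.inf)
            row += 1

        for k, cand in enumerate(self.candidates):
            _couple(self.cand_cols[cand.id], self.off_s + k)
        for k in range(n_rev):
            _couple([self.off_revflux + k], self.off_rev + k)
        if row:
            A_ind = sparse.coo_matrix(
                (c_vals, (c_rows, c_cols)), shape=(row, n_var)
            )
            constraints.append(LinearConstraint(A_ind.tocsr(), c_lo, c_hi))
        self.base_constraints = constraints

        # objective: action costs on the binaries plus the tie perturbation
        self.cand_costs = np.array(
            [candidate_cost(c, config) for c in self.candidates]
        )
        self.rev_costs = np.full(n_rev, config.w_reverse)
        eps = _tie_epsilons(n_cand + n_rev, config)
        cvec = np.zeros(n_var)
        cvec[self.off_s : self.off_rev] = self.cand_costs + eps[:n_cand]
        cvec[self.off_rev :] = self.rev_costs + eps[n_cand:]
        self.cvec = cvec
        self.n_var = n_var

    def solve(self, extra_constraints: Sequence[LinearConstraint] = ()):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # scipy forwards HiGHS-native options verbatim with a warning
            _warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                c=self.cvec,
                constraints=list(self.base_constraints) + list(extra_constraints),
                integrality=self.integrality,
                bounds=self.bounds,
                options={
                    "mip_rel_gap": self.config.mip_gap,
                    "time_limit": self.config.time_limit,
                    "presolve": True,
                    "mip_feasibility_tolerance": self.config.int_tol,
                    "primal_feasibility_tolerance": 1e-9,
                },
            )
        return res

    def extract(self, res) -> tuple:
        """(added, reversed, milp_state) from a solver result with a solution."""
        x = res.x
        s_vals, f_vals, rev_vals = {}, {}, {}
        for k, cand in enumerate(self.candidates):
            s_vals[cand.id] = float(x[self.off_s + k])
            f_vals[cand.id] = float(sum(x[j] for j in self.cand_cols[cand.id]))
        for k, rid in enumerate(self.rev_ids):
            rev_vals[rid] = float(x[self.off_rev + k])
        added = frozenset(
            cid for cid, v in s_vals.items() if v > 1 - self.config.int_tol - 0.5
        )
        reversed_ = frozenset(
            rid for rid, v in rev_vals.items() if v > 1 - self.config.int_tol - 0.5
        )
        cost = float(
            sum(self.cand_costs[k] for k, c in enumerate(self.candidates) if c.id in added)
            + self.config.w_reverse * len(reversed_)
        )
        return added, reversed_, s_vals, f_vals, rev_vals, cost

    def selection_cut(self, added: frozenset, reversed_: frozenset) -> LinearConstraint:
        """Integer cut excluding one particular (added, reversed) selection."""
        idx = [
            self.off_s + k
            for k, c in enumerate(self.candidates)
            if c.id in added
        ] + [self.off_rev + k for k, r in enumerate(self.rev_ids) if r in reversed_]
        a = np.zeros(self.n_var)
        a[idx] = 1.0
        return LinearConstraint(a[None, :], -np.inf, len(idx) - 1)

    def cost_cap(self, cap: float) -> LinearConstraint:
        a = np.zeros(self.n_var)
        a[self.off_s : self.off_rev] = self.cand_costs
        a[self.off_rev :] = self.rev_costs
        return LinearConstraint(a[None, :], -np.inf, cap)


def _empty_solution(model: MetabolicModel, config: GapFillConfig) -> GapFillSolution:
    from .verify import ViolationReport

    state = MILPState({}, {}, {}, "optimal", 0.0)
    return GapFillSolution(
        added=frozenset(),
        reversed=frozenset(),
        total_cost=0.0,
        flux_state=solve_fba(model),
        status="optimal",
        audit=ViolationReport((), True),
        milp_state=state,
    )


def _finalize(
    model: MetabolicModel,
    candidates: Sequence[ReactionSpec],
    config: GapFillConfig,
    added: frozenset,
    reversed_: frozenset,
    s_vals,
    f_vals,
    rev_vals,
    cost: float,
    solver_status: str,
) -> GapFillSolution:
    from .verify import audit_solution

    by_id = {c.id: c for c in candidates}
    completed = augmented(
        model, [by_id[r] for r in sorted(added)], relax_directions=reversed_
    )
    flux_state = solve_fba(completed)
    milp_state = MILPState(s_vals, f_vals, rev_vals, solver_status, cost)
    report = audit_solution(milp_state, config)
    status = solver_status
    if status == "optimal" and not (
        flux_state.status == "optimal"
        and flux_state.objective_value > config.biomass_threshold
    ):
        # the MILP claimed growth the independent LP cannot reproduce
        status = "feasible"
    return GapFillSolution(
        added=added,
        reversed=reversed_,
        total_cost=cost,
        flux_state=flux_state,
        status=status,
        audit=report,
        milp_state=milp_state,
    )


def _infeasible_solution(
    model: MetabolicModel, candidates: Sequence[ReactionSpec], config: GapFillConfig
) -> GapFillSolution:
    from .verify import ViolationReport

    full = augmented(model, candidates)
    producible = producible_biomass_subset(full, config.biomass_threshold)
    missing = frozenset(model.condition.biomass_ids) - producible
    return GapFillSolution(
        added=frozenset(),
        reversed=frozenset(),
        total_cost=float("inf"),
        flux_state=None,
        status="infeasible",
        audit=ViolationReport((), True),
        milp_state=None,
        unproducible=frozenset(missing),
    )


def gapfill(
    model: MetabolicModel,
    database: Iterable[ReactionSpec],
    config: GapFillConfig = GapFillConfig(),
) -> GapFillSolution:
    """Find a minimum-cost completion of ``model`` from ``database``.

    Returns an empty zero-cost solution when the model already grows (zero is
    the global minimum of a nonnegative objective).  When no completion
    exists, the returned solution has status ``infeasible`` and lists the
    biomass metabolites that remain unproducible even with the full database
    added.  Deterministic given the configuration.
    """
    if grows(model, config.biomass_threshold):
        return _empty_solution(model, config)
    candidates = _filtered_candidates(model, database, config)
    problem = _MilpProblem(model, candidates, config)
    res = problem.solve()
    if res.status == 0:
        added, reversed_, s, f, rev, cost = problem.extract(res)
        return _finalize(
            model, candidates, config, added, reversed_, s, f, rev, cost, "optimal"
        )
    if res.status == 2:
        return _infeasible_solution(model, candidates, config)
    if res.status == 1:  # hit time/iteration limit
        if res.x is not None:
            added, reversed_, s, f, rev, cost = problem.extract(res)
            sol = _finalize(
                model, candidates, config, added, reversed_, s, f, rev, cost, "timeout"
            )
            return sol
        return GapFillSolution(
            frozenset(), frozenset(), float("inf"), None, "timeout"
        )
    raise SolverError(f"MILP solver failed: {res.message} (status {res.status})")


def enumerate_equal_cost_solutions(
    model: MetabolicModel,
    database: Iterable[ReactionSpec],
    config: GapFillConfig = GapFillConfig(),
    limit: int = 10,
) -> list:
    """Up to ``limit`` distinct optimal-cost solutions, via integer-cut
    re-solving.  All returned solutions share the optimal total cost; the
    list is ordered by lexicographic added-set.  With ``limit=1`` this is
    exactly :func:`gapfill`."""
    if limit < 1:
        raise ValueError("limit must be a positive integer")
    first = gapfill(model, database, config)
    if first.status in ("infeasible", "timeout") or limit == 1:
        return [first]
    if not first.added and not first.reversed:
        return [first]  # already-growing model: the empty solution is unique
    candidates = _filtered_candidates(model, database, config)
    problem = _MilpProblem(model, candidates, config)
    best = first.total_cost
    cap = problem.cost_cap(best + max(1.0, abs(best)) * 1e-9 + 10 * config.tie_eps)
    cuts = [problem.selection_cut(first.added, first.reversed)]
    solutions = [first]
    while len(solutions) < limit:
        res = problem.solve(extra_constraints=[cap] + cuts)
        if res.status != 0:
            break
        added, reversed_, s, f, rev, cost = problem.extract(res)
        if cost > best + max(1.0, abs(best)) * 1e-6:
            break
        solutions.append(
            _finalize(
                model, candidates, config, added, reversed_, s, f, rev, cost, "optimal"
            )
        )
        cuts.append(problem.selection_cut(added, reversed_))
    solutions.sort(key=lambda sol: (sorted(sol.added), sorted(sol.reversed)))
    return solutions
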