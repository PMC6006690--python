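"""Steady-state flux balance analysis (FBA) on a :class:`MetabolicModel`.

FBA maximizes the flux of a lumped biomass demand reaction subject to
steady-state mass balance ``S v = 0`` and nonnegative split-column flux
bounds; the LP is solved with HiGHS.  A model "grows" when the optimal
biomass demand flux exceeds a small positive threshold (default 1e-3 flux
units), which guards against declaring growth on solver-noise-level fluxes.

Besides the joint biomass objective, the module can probe each biomass
metabolite individually (a single-metabolite demand LP per metabolite) to
report the producible subset — useful to diagnose why a gapped network
fails to grow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .netcore import (
    BIOMASS_COLUMN,
    DEFAULT_FLUX_BOUND,
    MatrixColumn,
    MetabolicModel,
    StoichiometricMatrix,
    build_matrix,
)

__all__ = [
    "FluxState",
    "SolverError",
    "GROWTH_THRESHOLD",
    "solve_fba",
    "grows",
    "producible_biomass_subset",
    "compare_growth",
]

#: Minimum biomass demand flux counted as growth.
GROWTH_THRESHOLD = 1e-3

#: Steady-state residual tolerance: an optimal solution must satisfy
#: |S v| <= EPS_MASS on every metabolite row.
EPS_MASS = 1e-6

#: Primal feasibility tolerance handed to HiGHS.
FEAS_TOL = 1e-9


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class FluxState:
    """Outcome of one FBA solve: net per-reaction fluxes, the biomass demand
    flux achieved, and the solver status."""

    fluxes: dict
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def active_reactions(self) -> set:
        return {r for r, f in self.fluxes.items() if abs(f) > GROWTH_THRESHOLD}


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _maximize_column(
    smat: StoichiometricMatrix, column: str, eps_mass: float = EPS_MASS
) -> tuple:
    """Maximize one flux column over {v >= 0 : S v = 0, v <= ub}; returns
    (status, objective, v)."""
    n = len(smat.columns)
    c = np.zeros(n)
    c[smat.column_index[column]] = -1.0  # linprog minimizes
    lb, ub = smat.column_bounds()
    res = linprog(
        c,
        A_eq=smat.matrix,
        b_eq=np.zeros(len(smat.rows)),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL},
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: {res.message} (status {res.status})")
    if status != "optimal":
        return status, 0.0, None
    v = res.x
    residual = np.abs(smat.matrix @ v)
    if residual.size and residual.max() > eps_mass:
        raise SolverError(
            f"steady-state residual {residual.max():.3g} exceeds {eps_mass:g}"
        )
    return status, float(-res.fun) + 0.0, v  # +0.0 normalizes IEEE -0.0


def solve_fba(model: MetabolicModel, flux_bound: float = DEFAULT_FLUX_BOUND) -> FluxState:
    """Maximize the lumped biomass demand flux of ``model``.

    Returns a :class:`FluxState`; with no biomass metabolites defined the
    objective is trivially 0.  Deterministic for a fixed solver configuration.
    """
    if not model.condition.biomass_metabolites:
        return FluxState({}, 0.0, "optimal")
    smat = build_matrix(model, flux_bound=flux_bound)
    status, obj, v = _maximize_column(smat, BIOMASS_COLUMN)
    fluxes = smat.net_fluxes(v) if v is not None else {}
    return FluxState(fluxes, obj, status)


def grows(model: MetabolicModel, threshold: float = GROWTH_THRESHOLD) -> bool:
    """True iff the maximal biomass demand flux strictly exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("growth threshold must be positive")
    state = solve_fba(model)
    return state.status == "optimal" and state.objective_value > threshold


def producible_biomass_subset(
    model: MetabolicModel, threshold: float = GROWTH_THRESHOLD
) -> set:
    """The biomass metabolites the network can actually synthesize.

    Each biomass metabolite is tested in isolation with its own demand column
    (the lumped biomass demand is left out); it is producible iff its maximal
    demand flux exceeds ``threshold``.  Order-independent by construction.
    """
    base = build_matrix(model, include_biomass_demand=False)
    producible = set()
    for met in model.condition.biomass_ids:
        col = MatrixColumn(f"DM_{met}__probe", "", "demand", 0.0, np.inf)
        entry = sparse.csc_matrix(
            ([-1.0], [base.row_index[met]], [0, 1]), shape=(len(base.rows), 1)
        )
        probe = StoichiometricMatrix(
            base.rows,
            base.columns + (col,),
            sparse.hstack([base.matrix, entry], format="csc"),
        )
        status, obj, _ = _maximize_column(probe, col.name)
        if status == "optimal" and obj > threshold:
            producible.add(met)
    return producible


def compare_growth(model: MetabolicModel, variant: MetabolicModel) -> float:
    """Growth-rate ratio objective(variant) / objective(model).

    Both models must share the biomass definition; the ratio is 0 when the
    variant does not grow, and a ``ValueError`` is raised when the baseline
    model itself does not grow (the ratio would be undefined).
    """
    if model.condition.biomass_metabolites != variant.condition.biomass_metabolites:
        raise ValueError("models have different biomass definitions")
    base = solve_fba(model)
    if base.status != "optimal" or base.objective_value <= GROWTH_THRESHOLD:
        raise ValueError("baseline model does not grow; growth ratio undefined")
    other = solve_fba(variant)
    if other.status != "optimal":
        return 0.0
    return other.objective_value / base.objective_value
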