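"""Core domain types and I/O for metabolic networks.

A network is a set of stoichiometric reactions over named metabolites,
accompanied by a model condition (nutrients, secretions, biomass metabolites)
that defines the growth environment.  Models are read and written either as
SBML Level 3 (via COBRApy) or as a compact tab-separated reaction table whose
rows are human-writable::

    id<TAB>equation<TAB>direction<TAB>in_taxon<TAB>is_polymer<TAB>gene_assoc

with equations like ``GLC + ATP -> G6P + ADP`` (omitted coefficients default
to 1, ``<->`` marks a reversible arrow).

Exchange and demand reactions are never part of the reaction table: they are
generated from the :class:`ModelCondition` when the stoichiometric matrix is
built, which keeps gap-filling candidate sets purely metabolic.
"""

from __future__ import annotations

import enum
import os
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Direction",
    "MetaboliteSpec",
    "ReactionSpec",
    "ModelCondition",
    "MetabolicModel",
    "StoichiometricMatrix",
    "MatrixColumn",
    "ModelFormatError",
    "ModelValidationError",
    "DirectionWarning",
    "read_model",
    "write_model",
    "read_condition",
    "write_condition",
    "parse_equation",
    "format_equation",
    "build_matrix",
    "augmented",
    "DEFAULT_FLUX_BOUND",
    "EXCHANGE_PREFIXES",
]

#: Upper flux bound used when a reaction or exchange has no explicit bound.
DEFAULT_FLUX_BOUND = 3000.0

#: Id prefixes marking exchange/demand/sink pseudo-reactions, which are exempt
#: from the "at least one substrate and one product" invariant.
EXCHANGE_PREFIXES = ("EX_", "DM_", "SK_")


class ModelFormatError(ValueError):
    """A model file could not be parsed in the requested format."""


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling ids, duplicates...)."""


class DirectionWarning(UserWarning):
    """A reaction arrived without an explicit direction and was made reversible."""


class Direction(enum.Enum):
    """Permitted flux direction of a reaction, relative to its written equation."""

    L2R = "L2R"
    R2L = "R2L"
    REVERSIBLE = "REVERSIBLE"


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite: unique id, display name, compartment (single cytosolic
    compartment ``c`` by default; compartment suffixes carry no transport
    semantics)."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")


@dataclass(frozen=True)
class ReactionSpec:
    """A stoichiometric reaction, the unit of gap filling.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    means consumed left-to-right, positive means produced.  ``direction`` is
    always explicit — parsers never leave it unset.  The two flags feed the
    gap filler's cost model: candidates outside the taxonomic range of the
    target organism cost more to insert, and polymerization/depolymerization
    reactions can be excluded from candidacy altogether.
    """

    id: str
    stoichiometry: Mapping[str, float]
    direction: Direction = Direction.REVERSIBLE
    in_taxonomic_range: bool = True
    is_polymerization: bool = False
    gene_associated: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        stoich = dict(self.stoichiometry)
        object.__setattr__(self, "stoichiometry", stoich)
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))
        if not self.is_exchange:
            has_neg = any(c < 0 for c in stoich.values())
            has_pos = any(c > 0 for c in stoich.values())
            if not (has_neg and has_pos):
                raise ModelValidationError(
                    f"reaction {self.id!r} must consume and produce at least one "
                    "metabolite (exchange/demand reactions use an "
                    f"{'/'.join(EXCHANGE_PREFIXES)} id prefix)"
                )

    @property
    def is_exchange(self) -> bool:
        return self.id.startswith(EXCHANGE_PREFIXES)

    def reversed(self) -> "ReactionSpec":
        """The same reaction constrained to run in the opposite direction."""
        flip = {Direction.L2R: Direction.R2L, Direction.R2L: Direction.L2R}
        return replace(self, direction=flip.get(self.direction, Direction.REVERSIBLE))

    def relaxed(self) -> "ReactionSpec":
        """The same reaction with its direction relaxed to reversible."""
        return replace(self, direction=Direction.REVERSIBLE)


@dataclass(frozen=True)
class ModelCondition:
    """Growth environment: bounded nutrient uptakes, free secretions, and the
    biomass metabolites the model must synthesize (coefficient defaults 1)."""

    nutrients: tuple = ()
    secretions: tuple = ()
    biomass_metabolites: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "nutrients", tuple((m, float(b)) for m, b in self.nutrients)
        )
        object.__setattr__(self, "secretions", tuple(self.secretions))
        object.__setattr__(
            self,
            "biomass_metabolites",
            tuple((m, float(c)) for m, c in self.biomass_metabolites),
        )
        for met, bound in self.nutrients:
            if bound < 0:
                raise ModelValidationError(f"nutrient {met!r} has negative uptake bound")
        for met, coef in self.biomass_metabolites:
            if coef <= 0:
                raise ModelValidationError(f"biomass coefficient for {met!r} must be > 0")

    @property
    def biomass_ids(self) -> tuple:
        return tuple(m for m, _ in self.biomass_metabolites)

    def referenced_ids(self) -> set:
        return (
            {m for m, _ in self.nutrients}
            | set(self.secretions)
            | {m for m, _ in self.biomass_metabolites}
        )


@dataclass(frozen=True)
class MetabolicModel:
    """A metabolic network plus its model condition.

    Metabolites and reactions are stored as insertion-ordered id -> spec maps;
    ids are case-sensitive and duplicates are a hard error at construction.
    """

    metabolites: Mapping[str, MetaboliteSpec]
    reactions: Mapping[str, ReactionSpec]
    condition: ModelCondition = ModelCondition()

    def __post_init__(self) -> None:
        mets = _as_id_map(self.metabolites, "metabolite")
        rxns = _as_id_map(self.reactions, "reaction")
        object.__setattr__(self, "metabolites", mets)
        object.__setattr__(self, "reactions", rxns)
        dangling = sorted(
            {m for r in rxns.values() for m in r.stoichiometry} - mets.keys()
        )
        if dangling:
            raise ModelValidationError(
                f"reactions reference unknown metabolites: {', '.join(dangling)}"
            )
        missing = sorted(self.condition.referenced_ids() - mets.keys())
        if missing:
            raise ModelValidationError(
                f"model condition references unknown metabolites: {', '.join(missing)}"
            )

    def with_condition(self, condition: ModelCondition) -> "MetabolicModel":
        return MetabolicModel(self.metabolites, self.reactions, condition)

    def without_reactions(self, ids: Iterable[str]) -> "MetabolicModel":
        drop = set(ids)
        kept = {k: v for k, v in self.reactions.items() if k not in drop}
        return MetabolicModel(self.metabolites, kept, self.condition)


def _as_id_map(items, what: str) -> dict:
    if isinstance(items, Mapping):
        for key, spec in items.items():
            if key != spec.id:
                raise ModelValidationError(f"{what} map key {key!r} != spec id {spec.id!r}")
        return dict(items)
    out: dict = {}
    for spec in items:
        if spec.id in out:
            raise ModelValidationError(f"duplicate {what} id {spec.id!r}")
        out[spec.id] = spec
    return out


def augmented(
    model: MetabolicModel,
    additions: Iterable[ReactionSpec] = (),
    relax_directions: Iterable[str] = (),
) -> MetabolicModel:
    """Model plus extra reactions, with selected existing reactions relaxed to
    reversible.  Metabolites referenced only by the additions are created on
    the fly (bare specs in the default compartment)."""
    additions = list(additions)
    relax = set(relax_directions)
    unknown = relax - model.reactions.keys()
    if unknown:
        raise ModelValidationError(f"cannot relax unknown reactions: {sorted(unknown)}")
    mets = dict(model.metabolites)
    for rxn in additions:
        for mid in rxn.stoichiometry:
            if mid not in mets:
                mets[mid] = MetaboliteSpec(mid)
    rxns = {
        rid: (spec.relaxed() if rid in relax else spec)
        for rid, spec in model.reactions.items()
    }
    for rxn in additions:
        if rxn.id in rxns:
            raise ModelValidationError(f"added reaction id {rxn.id!r} already in model")
        rxns[rxn.id] = rxn
    return MetabolicModel(mets, rxns, model.condition)


# ---------------------------------------------------------------------------
# Reaction-equation grammar
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "->")
_NUMBER = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def parse_equation(text: str):
    """Parse ``coef met + ... -> coef met + ...`` into (stoichiometry, reversible).

    Coefficients are optional (default 1) and must precede the metabolite id.
    ``<->`` marks the arrow of a reversible reaction.
    """
    text = text.strip()
    arrow = None
    for cand in _ARROWS:
        if cand in text:
            arrow = cand
            break
    if arrow is None:
        raise ModelFormatError(f"equation lacks an arrow ('->' or '<->'): {text!r}")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"empty term in equation {text!r}")
            parts = term.split(None, 1)
            if len(parts) == 2 and _NUMBER.match(parts[0]):
                coef, met = float(parts[0]), parts[1].strip()
            else:
                coef, met = 1.0, term
            if " " in met:
                raise ModelFormatError(f"metabolite id {met!r} contains whitespace")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _accumulate(lhs, -1.0)
    _accumulate(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}, arrow == "<->"


def _fmt_coef(c: float) -> str:
    if c == int(c):
        return "" if c == 1 else f"{int(c)} "
    return f"{c:g} "


def format_equation(rxn: ReactionSpec) -> str:
    subs = sorted((m, -c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<->" if rxn.direction is Direction.REVERSIBLE else "->"
    left = " + ".join(f"{_fmt_coef(c)}{m}" for m, c in subs)
    right = " + ".join(f"{_fmt_coef(c)}{m}" for m, c in prods)
    return f"{left} {arrow} {right}".strip()


# ---------------------------------------------------------------------------
# TSV reaction-table dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = ["id", "equation", "direction", "in_taxon", "is_polymer", "gene_assoc"]
_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _parse_bool(text: str, where: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ModelFormatError(f"{where}: cannot parse boolean {text!r}")


def _read_tsv(path) -> list:
    reactions = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip() == "id":
                continue  # header
            if len(fields) < 2:
                raise ModelFormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            fields += [""] * (len(_TSV_HEADER) - len(fields))
            rid, equation, direction, in_taxon, is_polymer, gene_assoc = fields[:6]
            rid = rid.strip()
            try:
                stoich, rev_arrow = parse_equation(equation)
            except ModelFormatError as exc:
                raise ModelFormatError(f"{path}:{lineno}: {exc}") from exc
            dtext = direction.strip().upper()
            if dtext:
                try:
                    direction_ = Direction(dtext)
                except ValueError as exc:
                    raise ModelFormatError(
                        f"{path}:{lineno}: unknown direction {direction!r}"
                    ) from exc
            elif rev_arrow:
                direction_ = Direction.REVERSIBLE
            else:
                # Unset directions are never silently inferred: the reaction is
                # made reversible and the caller is warned.
                direction_ = Direction.REVERSIBLE
                warnings.warn(
                    f"{path}:{lineno}: reaction {rid!r} has no explicit direction; "
                    "treating as REVERSIBLE",
                    DirectionWarning,
                    stacklevel=3,
                )
            try:
                reactions.append(
                    ReactionSpec(
                        id=rid,
                        stoichiometry=stoich,
                        direction=direction_,
                        in_taxonomic_range=_parse_bool(in_taxon, f"{path}:{lineno}"),
                        is_polymerization=_parse_bool(is_polymer, f"{path}:{lineno}"),
                        gene_associated=_parse_bool(gene_assoc, f"{path}:{lineno}"),
                    )
                )
            except ModelValidationError as exc:
                raise ModelFormatError(f"{path}:{lineno}: {exc}") from exc
    return reactions


def _write_tsv(model: MetabolicModel, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for rxn in model.reactions.values():
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        format_equation(rxn),
                        rxn.direction.value,
                        str(rxn.in_taxonomic_range).lower(),
                        str(rxn.is_polymerization).lower(),
                        str(rxn.gene_associated).lower(),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SBML via COBRApy (Level 3 + fbc flux bounds)
# ---------------------------------------------------------------------------

_FLAG_NOTES = {
    "in_taxonomic_range": "in_taxonomic_range",
    "is_polymerization": "is_polymerization",
    "gene_associated": "gene_associated",
}


def _read_sbml(path) -> tuple:
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports rich parse errors
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc

    mets = [
        MetaboliteSpec(m.id, m.name or "", m.compartment or "c")
        for m in cmodel.metabolites
    ]
    rxns = []
    for r in cmodel.reactions:
        if r.id.startswith(EXCHANGE_PREFIXES) or r.boundary:
            continue  # exchanges are condition-derived, never read from file
        lb, ub = r.lower_bound, r.upper_bound
        if lb < 0 and ub > 0:
            direction = Direction.REVERSIBLE
        elif ub > 0:
            direction = Direction.L2R
        elif lb < 0:
            direction = Direction.R2L
        else:
            direction = Direction.REVERSIBLE
            warnings.warn(
                f"SBML reaction {r.id!r} has zero flux bounds; treating as REVERSIBLE",
                DirectionWarning,
                stacklevel=3,
            )
        notes = {str(k).strip(): str(v).strip().lower() for k, v in r.notes.items()}
        rxns.append(
            ReactionSpec(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                direction=direction,
                in_taxonomic_range=notes.get("in_taxonomic_range", "true") in _TRUE,
                is_polymerization=notes.get("is_polymerization", "false") in _TRUE,
                gene_associated=notes.get("gene_associated", "false") in _TRUE,
            )
        )
    return mets, rxns


def _write_sbml(model: MetabolicModel, path) -> None:
    import cobra
    import cobra.io

    cmodel = cobra.Model("model")
    cmets = {}
    for m in model.metabolites.values():
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id)
        if r.direction is Direction.L2R:
            cr.bounds = (0.0, DEFAULT_FLUX_BOUND)
        elif r.direction is Direction.R2L:
            cr.bounds = (-DEFAULT_FLUX_BOUND, 0.0)
        else:
            cr.bounds = (-DEFAULT_FLUX_BOUND, DEFAULT_FLUX_BOUND)
        cr.notes = {
            "in_taxonomic_range": str(r.in_taxonomic_range).lower(),
            "is_polymerization": str(r.is_polymerization).lower(),
            "gene_associated": str(r.gene_associated).lower(),
        }
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions.values():
        cmodel.reactions.get_by_id(r.id).add_metabolites(
            {cmets[m]: c for m, c in r.stoichiometry.items()}
        )
    cobra.io.write_sbml_model(cmodel, str(path))


# ---------------------------------------------------------------------------
# Model condition file: NUTRIENTS / SECRETIONS / BIOMASS sections
# ---------------------------------------------------------------------------

_SECTIONS = ("NUTRIENTS", "SECRETIONS", "BIOMASS")
#: Default per-nutrient uptake bound (flux units) when the condition file
#: gives none; any positive bound preserves qualitative growth results.
DEFAULT_UPTAKE_BOUND = 10.0


def read_condition(path) -> ModelCondition:
    """Parse a plain-text condition file with ``NUTRIENTS``, ``SECRETIONS``
    and ``BIOMASS`` sections, one metabolite id (plus optional number:
    uptake bound for nutrients, coefficient for biomass) per line."""
    nutrients, secretions, biomass = [], [], []
    section = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper() in _SECTIONS:
                section = line.upper()
                continue
            if section is None:
                raise ModelFormatError(
                    f"{path}:{lineno}: entry before any section header "
                    f"({'/'.join(_SECTIONS)})"
                )
            parts = line.split()
            met = parts[0]
            number = None
            if len(parts) > 1:
                try:
                    number = float(parts[1])
                except ValueError as exc:
                    raise ModelFormatError(
                        f"{path}:{lineno}: cannot parse number {parts[1]!r}"
                    ) from exc
            if section == "NUTRIENTS":
                nutrients.append((met, DEFAULT_UPTAKE_BOUND if number is None else number))
            elif section == "SECRETIONS":
                secretions.append(met)
            else:
                biomass.append((met, 1.0 if number is None else number))
    return ModelCondition(nutrients, secretions, biomass)


def write_condition(condition: ModelCondition, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("NUTRIENTS\n")
        for met, bound in condition.nutrients:
            fh.write(f"{met} {bound:g}\n")
        fh.write("SECRETIONS\n")
        for met in condition.secretions:
            fh.write(f"{met}\n")
        fh.write("BIOMASS\n")
        for met, coef in condition.biomass_metabolites:
            fh.write(f"{met} {coef:g}\n")


# ---------------------------------------------------------------------------
# read_model / write_model front doors
# ---------------------------------------------------------------------------


def read_model(path, format: str = None, condition=None) -> MetabolicModel:
    """Read a metabolic model from ``path`` in the named format.

    Parameters
    ----------
    path:
        Model file (TSV reaction table or SBML).
    format:
        ``"tsv"`` or ``"sbml"``; inferred from the file extension when None.
    condition:
        A :class:`ModelCondition`, or a path to a condition file, or None for
        an empty condition (no nutrients, secretions or biomass).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "tsv"
    if format == "tsv":
        rxns = _read_tsv(path)
        mets = {}
        for r in rxns:
            for mid in r.stoichiometry:
                mets.setdefault(mid, MetaboliteSpec(mid))
        mets_list = list(mets.values())
    elif format == "sbml":
        mets_list, rxns = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    if condition is None:
        cond = ModelCondition()
    elif isinstance(condition, ModelCondition):
        cond = condition
    else:
        cond = read_condition(condition)
    # metabolites named only by the condition (e.g. TSV fixtures whose nutrient
    # is consumed by no reaction) are created so validation can proceed
    mets_map = {m.id: m for m in mets_list}
    for mid in cond.referenced_ids():
        mets_map.setdefault(mid, MetaboliteSpec(mid))
    return MetabolicModel(mets_map, rxns, cond)


def write_model(model: MetabolicModel, path, format: str = None) -> None:
    """Write ``model`` to ``path``; losslessly inverted by :func:`read_model`
    for ids, stoichiometries, directions and flags.  The model condition is
    not part of either format (see :func:`write_condition`)."""
    path = os.fspath(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "tsv"
    if format == "tsv":
        _write_tsv(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Stoichiometric matrix with direction-split columns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatrixColumn:
    """One flux variable: a direction-split reaction column or a
    condition-derived exchange/demand column, with its [lb, ub] bounds."""

    name: str
    reaction_id: str  # "" for condition-derived columns
    kind: str  # forward | backward | uptake | export | demand
    lb: float
    ub: float


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Sparse steady-state matrix S with all flux variables nonnegative.

    Reversible reactions are split into forward and backward columns (the
    backward column is the entrywise negation of the forward one); nutrient
    uptakes, secretions and the lumped biomass demand are appended as
    condition-derived columns.  A flux vector v over the columns satisfies
    steady state iff S @ v == 0.
    """

    rows: tuple  # metabolite ids
    columns: tuple  # MatrixColumn
    matrix: sparse.csc_matrix

    @property
    def row_index(self) -> dict:
        return {m: i for i, m in enumerate(self.rows)}

    @property
    def column_index(self) -> dict:
        return {c.name: i for i, c in enumerate(self.columns)}

    def column_bounds(self) -> tuple:
        lb = np.array([c.lb for c in self.columns])
        ub = np.array([c.ub for c in self.columns])
        return lb, ub

    def net_fluxes(self, v: np.ndarray) -> dict:
        """Collapse split columns back to net per-reaction fluxes."""
        out: dict = {}
        for col, value in zip(self.columns, v):
            if col.kind == "forward":
                out[col.reaction_id] = out.get(col.reaction_id, 0.0) + value
            elif col.kind == "backward":
                out[col.reaction_id] = out.get(col.reaction_id, 0.0) - value
        return out


BIOMASS_COLUMN = "DM_biomass"


def build_matrix(
    model: MetabolicModel,
    flux_bound: float = DEFAULT_FLUX_BOUND,
    include_biomass_demand: bool = True,
) -> StoichiometricMatrix:
    """Build the steady-state matrix for ``model``.

    Columns: one per irreversible reaction (forward for L2R, backward for
    R2L), two per reversible reaction, one bounded uptake per nutrient, one
    unbounded export per secretion, and (optionally) one biomass demand
    column consuming every biomass metabolite in its coefficient.
    """
    rows = tuple(model.metabolites)
    ridx = {m: i for i, m in enumerate(rows)}
    columns: list = []
    data, indices, indptr = [], [], [0]

    def _push(col: MatrixColumn, entries: Mapping[str, float]) -> None:
        columns.append(col)
        for met, coef in entries.items():
            indices.append(ridx[met])
            data.append(coef)
        indptr.append(len(data))

    for rxn in model.reactions.values():
        if rxn.direction in (Direction.L2R, Direction.REVERSIBLE):
            _push(
                MatrixColumn(f"{rxn.id}__fwd", rxn.id, "forward", 0.0, flux_bound),
                rxn.stoichiometry,
            )
        if rxn.direction in (Direction.R2L, Direction.REVERSIBLE):
            _push(
                MatrixColumn(f"{rxn.id}__bwd", rxn.id, "backward", 0.0, flux_bound),
                {m: -c for m, c in rxn.stoichiometry.items()},
            )
    for met, bound in model.condition.nutrients:
        _push(MatrixColumn(f"EX_{met}__uptake", "", "uptake", 0.0, bound), {met: 1.0})
    for met in model.condition.secretions:
        _push(MatrixColumn(f"EX_{met}__export", "", "export", 0.0, np.inf), {met: -1.0})
    if include_biomass_demand and model.condition.biomass_metabolites:
        _push(
            MatrixColumn(BIOMASS_COLUMN, "", "demand", 0.0, np.inf),
            {m: -c for m, c in model.condition.biomass_metabolites},
        )
    mat = sparse.csc_matrix(
        (data, indices, indptr), shape=(len(rows), len(columns))
    )
    return StoichiometricMatrix(rows, tuple(columns), mat)
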