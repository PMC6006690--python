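"""Synthetic gap-filling benchmarks with known ground truth.

Real gap-filling studies need an organism database and a curated reference
network; for testing and calibration this module generates the whole setting
instead: a ground-truth network that grows (nutrient-rooted directed
pathways reaching every biomass metabolite, plus redundant branch routes), a
gapped variant obtained by deleting reactions that are *essential* for
growth (so the gapped network provably fails), and a candidate database
containing the deleted reactions alongside decoys.

Decoys come in two kinds, both incapable of spuriously completing the
network on the cheap:

* ``disconnected`` — a conversion between fresh metabolites no other
  reaction produces, so it can never carry steady-state flux;
* ``duplicate`` — a copy of a deleted reaction under another id, flagged
  outside the taxonomic range and therefore strictly costlier than the
  original.

With that construction the deleted set is the unique minimum-cost
completion, so a correct gap filler must recover it exactly — the basis of
the recall/precision recovery tests.  An ``allow_ambiguous`` switch permits
equal-cost in-taxon duplicates for tie-breaking studies.

All randomness flows from a single seed through numpy's counter-based
Philox generator; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fba import grows
from .netcore import (
    Direction,
    MetaboliteSpec,
    MetabolicModel,
    ModelCondition,
    ReactionSpec,
)

__all__ = [
    "SynthParams",
    "Benchmark",
    "GenerationError",
    "generate_truth",
    "make_benchmark",
    "essential_reactions",
    "plant_redundant_solution",
]

#: Per-nutrient uptake bound used by generated conditions (flux units).
NUTRIENT_BOUND = 10.0


class GenerationError(RuntimeError):
    """An internal consistency check of the generator failed (bug guard)."""


@dataclass(frozen=True)
class SynthParams:
    """Shape of a generated ground-truth network.

    The backbone is a set of directed conversions that makes every
    non-nutrient metabolite reachable from the nutrients (requiring at least
    ``n_metabolites - n_nutrients`` backbone reactions); branch reactions add
    redundant parallel routes.  ``reversible_fraction`` of all reactions are
    relaxed to reversible.
    """

    n_metabolites: int = 20
    n_backbone_reactions: int = 18
    n_branch_reactions: int = 6
    n_biomass: int = 3
    n_nutrients: int = 2
    reversible_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_biomass < 1 or self.n_nutrients < 1:
            raise ValueError("need at least one biomass metabolite and one nutrient")
        if min(self.n_metabolites, self.n_backbone_reactions) < 1:
            raise ValueError("counts must be positive")
        if self.n_branch_reactions < 0 or not 0 <= self.reversible_fraction <= 1:
            raise ValueError("invalid branch count or reversible fraction")
        if self.n_nutrients + self.n_biomass > self.n_metabolites:
            raise ValueError("nutrients + biomass exceed metabolite count")
        if self.n_backbone_reactions < self.n_metabolites - self.n_nutrients:
            raise ValueError(
                "need >= n_metabolites - n_nutrients backbone reactions to reach "
                "every metabolite"
            )


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def generate_truth(params: SynthParams) -> MetabolicModel:
    """Generate a growing ground-truth network; deterministic given the seed.

    Metabolites are ordered; the first ``n_nutrients`` are nutrients and the
    last ``n_biomass`` are biomass metabolites.  Every backbone reaction
    produces one later-ordered metabolite from one or two earlier ones, which
    guarantees reachability (and hence growth, re-verified by FBA before
    returning).
    """
    rng = _rng(params.seed)
    n = params.n_metabolites
    mets = [f"M{i:03d}" for i in range(n)]
    nutrients = mets[: params.n_nutrients]
    biomass = mets[n - params.n_biomass :]
    reactions = []

    def _conversion(rid: str, substrates, product) -> ReactionSpec:
        stoich: dict = {}
        for s in substrates:
            stoich[s] = stoich.get(s, 0.0) - 1.0
        stoich[product] = stoich.get(product, 0.0) + 1.0
        return ReactionSpec(
            id=rid,
            stoichiometry=stoich,
            direction=Direction.L2R,
            in_taxonomic_range=True,
            gene_associated=True,
        )

    # coverage backbone: one producing reaction per non-nutrient metabolite
    k = 0
    for i in range(params.n_nutrients, n):
        n_sub = 1 if i == params.n_nutrients or rng.random() < 0.7 else 2
        subs = rng.choice(i, size=min(n_sub, i), replace=False)
        reactions.append(_conversion(f"RB{k:03d}", [mets[j] for j in subs], mets[i]))
        k += 1
    # extra backbone conversions between already-placed metabolites
    while k < params.n_backbone_reactions:
        i = int(rng.integers(params.n_nutrients, n))
        j = int(rng.integers(0, i))
        reactions.append(_conversion(f"RB{k:03d}", [mets[j]], mets[i]))
        k += 1
    # redundant branch routes
    for b in range(params.n_branch_reactions):
        i = int(rng.integers(params.n_nutrients, n))
        j = int(rng.integers(0, i))
        reactions.append(_conversion(f"RR{b:03d}", [mets[j]], mets[i]))
    # relax a fraction to reversible (1-to-1 conversions cannot create mass,
    # so cycles introduced this way are harmless)
    flip = rng.random(len(reactions)) < params.reversible_fraction
    reactions = [
        replace(r, direction=Direction.REVERSIBLE) if f else r
        for r, f in zip(reactions, flip)
    ]
    condition = ModelCondition(
        nutrients=[(m, NUTRIENT_BOUND) for m in nutrients],
        secretions=(),
        biomass_metabolites=[(m, 1.0) for m in biomass],
    )
    model = MetabolicModel(
        [MetaboliteSpec(m) for m in mets], reactions, condition
    )
    if not grows(model):
        raise GenerationError("generated ground-truth network fails its growth check")
    return model


def essential_reactions(model: MetabolicModel) -> set:
    """Reactions whose single deletion stops growth (single-deletion FBA)."""
    return {
        rid
        for rid in model.reactions
        if not grows(model.without_reactions([rid]))
    }


@dataclass(frozen=True)
class Benchmark:
    """A gapped-network benchmark: ground truth, its non-growing gapped
    variant, the known deleted set, and a candidate database ⊇ deleted plus
    decoys.  ``decoy_kinds`` maps decoy ids to ``disconnected`` or
    ``duplicate``."""

    truth: MetabolicModel
    gapped: MetabolicModel
    deleted: frozenset
    database: tuple
    decoy_kinds: Mapping[str, str] = field(default_factory=dict)

    @property
    def database_ids(self) -> frozenset:
        return frozenset(r.id for r in self.database)


def make_benchmark(
    truth: MetabolicModel,
    n_delete: int,
    n_decoys: int = 0,
    decoy_out_taxon_fraction: float = 0.5,
    seed: int = 0,
    allow_ambiguous: bool = False,
) -> Benchmark:
    """Delete ``n_delete`` essential reactions from ``truth`` and build the
    candidate database.

    The deleted reactions enter the database in-taxon (cost of an ordinary
    insertion); decoys receive taxon flags so that roughly
    ``decoy_out_taxon_fraction`` of them are out-of-taxon.  Unless
    ``allow_ambiguous`` is set, every duplicate decoy is out-of-taxon, which
    keeps the deleted set the unique minimum-cost completion.  The database
    ordering is shuffled deterministically from the seed.
    """
    if n_delete < 1:
        raise ValueError("n_delete must be >= 1")
    rng = _rng(seed)
    essential = sorted(essential_reactions(truth))
    if len(essential) < n_delete:
        raise ValueError(
            f"truth has only {len(essential)} essential reactions; "
            f"cannot delete {n_delete}"
        )
    deleted = frozenset(
        str(r) for r in rng.choice(essential, size=n_delete, replace=False)
    )
    gapped = truth.without_reactions(deleted)
    if grows(gapped):
        raise GenerationError("gapped network still grows after deleting essentials")

    database = [
        replace(truth.reactions[rid], in_taxonomic_range=True, gene_associated=False)
        for rid in sorted(deleted)
    ]
    decoy_kinds: dict = {}
    deleted_sorted = sorted(deleted)
    for i in range(n_decoys):
        did = f"DEC{i:03d}"
        out_taxon = bool(rng.random() < decoy_out_taxon_fraction)
        dup_ok = out_taxon or allow_ambiguous
        if dup_ok and deleted_sorted and rng.random() < 0.5:
            src = truth.reactions[deleted_sorted[int(rng.integers(len(deleted_sorted)))]]
            decoy = replace(
                src, id=did, in_taxonomic_range=not out_taxon, gene_associated=False
            )
            decoy_kinds[did] = "duplicate"
        else:
            decoy = ReactionSpec(
                id=did,
                stoichiometry={f"D{i:03d}a": -1.0, f"D{i:03d}b": 1.0},
                direction=Direction.L2R,
                in_taxonomic_range=not out_taxon,
                gene_associated=False,
            )
            decoy_kinds[did] = "disconnected"
        database.append(decoy)
    order = rng.permutation(len(database))
    database = tuple(database[i] for i in order)
    return Benchmark(truth, gapped, deleted, database, decoy_kinds)


def plant_redundant_solution(benchmark: Benchmark, k: int, seed: int = 0) -> frozenset:
    """A deliberately non-minimal solution: the deleted set plus ``k``
    flux-incapable (disconnected) decoys from the database.

    Mirrors the situation where a gap filler returns extra reactions that a
    growth check cannot justify; greedy minimality verification must remove
    exactly the ``k`` planted reactions.
    """
    disconnected = sorted(
        did for did, kind in benchmark.decoy_kinds.items() if kind == "disconnected"
    )
    if len(disconnected) < k:
        raise ValueError(
            f"benchmark has only {len(disconnected)} disconnected decoys; need {k}"
        )
    rng = _rng(seed)
    extras = {str(x) for x in rng.choice(disconnected, size=k, replace=False)}
    return frozenset(benchmark.deleted | extras)
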