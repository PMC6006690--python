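# Methods

## Network representation

A model is a set of stoichiometric reactions over named metabolites plus a
*model condition*: bounded nutrient uptakes, free secretions, and the
biomass metabolites the network must synthesize. Reactions carry three
flags that feed the gap filler's cost model — taxonomic-range membership,
polymerization, and gene association — and an always-explicit direction
(`L2R`, `R2L`, `REVERSIBLE`). Parsers never infer a missing direction:
automatic direction inference is a documented source of unpredictability in
model building, so an unset direction becomes `REVERSIBLE` with a warning,
and direction curation is left to the modeler. A single cytosolic
compartment is assumed; compartment suffixes are tolerated but carry no
transport semantics, since transport modeling is inherently a manual
curation problem.

Exchange and demand pseudo-reactions are generated from the condition when
the stoichiometric matrix is built and are never part of reaction tables or
candidate databases; this keeps gap-filling candidates purely metabolic.
Models round-trip through SBML Level 3 (flux-bound encoding of direction,
flags in reaction notes) and through a minimal TSV reaction dialect designed
to keep test fixtures human-writable.

## Flux balance analysis

Reversible reactions are split into nonnegative forward/backward columns;
the steady-state LP `max v_biomass s.t. S v = 0, 0 <= v <= u` is solved with
HiGHS (primal feasibility 1e-9). An optimal solution is accepted only if
every mass-balance residual is below `eps_mass = 1e-6`. Growth means
biomass flux strictly above `1e-3` flux units; the threshold guards against
reading solver noise as growth and doubles as the lower active-flux bound of
the gap filler. When a nutrient uptake bound is unstated it defaults to 10
flux units — any positive bound preserves the qualitative growth answers,
and 10 gives readable flux values. The default reaction flux cap is 3000.

Biomass is modeled two ways, used for different questions: a single lumped
demand consuming all biomass metabolites jointly (growth tests, gap
filling, unit coefficients by default), and per-metabolite single demands
for reporting which biomass metabolites are individually producible —
the diagnostic that explains *why* a gapped model fails.

## Gap filling MILP

Candidates get a binary `s_r` coupled to their (split-column-summed) flux by
`B_l s_r <= f_r <= B_u s_r` with `B_l = 1e-3`, `B_u = 3000`. Reversal of an
existing irreversible reaction is an extra flux column in the forbidden
direction gated the same way by a reversal binary. The objective minimizes
`sum c_r s_r + w_reverse * sum rev_q` with default weights 1 (reverse) < 2
(insert in-taxon) < 4 (insert out-of-taxon); only the strict ordering is
semantically meaningful. Polymerization candidates are excluded by default
(their generic polymer stoichiometry is not instance-level mass-balanced).
The strict growth inequality is encoded as `>= threshold + 1e-9`, since an
LP cannot express strict inequalities.

Numerical choices that matter:

* **Integrality tolerance.** The MIP feasibility tolerance is 1e-9 by
  default, chosen so that `B_u * tol << B_l`. At the more conventional 1e-6
  a binary accepted at tolerance distance from zero admits flux up to
  `B_u * 1e-6 = 3e-3 >= B_l` through the indicator coupling, and the solver
  then systematically returns "deselected" candidates carrying active flux —
  reproducible here on a three-metabolite toy network and kept available
  (`int_tol` is configurable) because the package's audit exists precisely
  to catch it.
* **Tie-breaking.** Equal-cost optima are resolved by a tiny strictly
  increasing per-binary cost perturbation (1e-6 scale, ordered by reaction
  id), making the default behavior deterministic with a preference for
  lexicographically smallest sets. `randomize_ties` shuffles the
  perturbation order from the seed to emulate solvers that pick among ties
  arbitrarily. The reported `total_cost` is always recomputed from the
  unperturbed weights.
* **Never trust the MILP.** Every solution is re-validated by an
  independent LP growth check on the completed model and audited against
  the indicator constraints from the raw variable values; a solution whose
  LP re-check fails is downgraded from `optimal` to `feasible`.

Equal-cost solution enumeration re-solves under integer cuts (excluding
each found selection) with the cost capped at the optimum, until the cut
problem becomes infeasible or the requested limit is reached.

## Verification

`audit_solution` is a pure function of the MILP variable values: it flags
`s_r = 0` with `|f_r| >= B_l` (lower violation) and `s_r = 1` with
`|f_r| > B_u + 1e-6` (upper violation).

`verify_minimality` greedily deletes solution reactions in descending cost
order (ties by ascending id), keeping a deletion when FBA still certifies
growth. The output is *minimal* — every member essential — but not
necessarily *minimum-cost*: greedy removal can keep two cheap reactions
that jointly substitute one expensive one, a distinction the test suite
demonstrates constructively. Removal order is a genuine free choice (no
canonical order exists); descending cost is used because it biases toward
discarding expensive redundancy first, and the order is exposed rather than
hidden.

`brute_force_min_gapfill` enumerates candidate subsets in increasing
(cost, size, lexicographic) order and returns the first that restores
growth — exact by construction, guarded to databases of at most 20
candidates, and used throughout the tests as the independent optimality
oracle for the MILP (the two never share a code path beyond the FBA
growth check).

## Synthetic benchmarks

The generator emulates the gapped-network setting end to end. Ground truth
is built as nutrient-rooted directed pathways: metabolites are ordered,
each non-nutrient metabolite receives a producing conversion from one or
two earlier metabolites (guaranteeing reachability and hence growth, which
is re-verified by FBA before returning), and branch reactions add redundant
parallel routes. A configurable fraction of reactions is relaxed to
reversible; because all conversions are coefficient-1, the cycles this can
create conserve mass and cannot generate flux from nothing. Defaults (20
metabolites, 18 backbone + 6 branch reactions, 2 nutrients, 3 biomass
metabolites, 20% reversible) give networks small enough for exhaustive
oracle comparison yet rich enough to have redundancy.

Benchmarks delete a seeded choice of reactions *essential* to growth
(single-deletion FBA), so the gapped variant provably fails, and assemble a
candidate database of the deleted reactions (in-taxon) plus decoys of two
kinds: *disconnected* conversions between fresh metabolites that can never
carry steady-state flux, and *duplicates* of deleted reactions under new
ids flagged out-of-taxon, hence strictly costlier. By construction no decoy
can complete the network as cheaply as the deleted set, making the deleted
set the unique minimum-cost completion — the basis for exact-recovery
(recall = precision = 1) tests. An `allow_ambiguous` switch admits
equal-cost in-taxon duplicates for studying tie-breaking. Planted-redundancy
solutions (deleted set plus k disconnected decoys) exercise minimality
verification with a known answer: exactly k removals.

All generator randomness flows from one seed through numpy's counter-based
Philox generator; no global random state is read or written.

What the generator does *not* emulate: real reaction chemistry and element
balance, compartments and transport, generic-reaction instantiation, cofactor
coupling, and database-scale candidate sets (thousands of reactions).
Passing recovery tests on these benchmarks therefore demonstrates
correctness of the optimization and verification machinery — not that
gap-filled reactions in a real organism are biologically right, which the
packaged automated-vs-manual comparison (recall 61.5%, precision 66.6% on
exact-id scoring) shows they frequently are not.

## Reference tables

Three tables from the published *B. longum* gap-filling comparison are
packaged as TSV data: the 53 biomass metabolites (15 producible before gap
filling), the automated 12-reaction and manual 13-reaction solutions (two
automated reactions starred as excess, leaving the 10-reaction minimum
set), and the 28 direction-curated reactions. Loading verifies these counts
as an integrity check. The source publication states both "53" and "all 54"
for the biomass metabolite count in different places; the packaged table
follows the itemized 53-row listing and the discrepancy is noted here
rather than resolved. Percentages are formatted by truncation (not
rounding) to one decimal place to stay byte-comparable with the published
presentation, whose printed 66.6% corresponds to 8/12.

Evaluation uses exact-id matching only. Near-equivalent pairs — distinct
database ids for essentially the same transformation — are reported
informationally by an identical-stoichiometry scan but never merged into
the tp/fp/fn counts.

## Problem sizes

The oracle-equivalence sweep uses 200 seeded benchmarks of 14 metabolites
and at most 12 candidates each, sized so the brute-force oracle (up to
2^12 subsets per instance, pruned by cost ordering) remains exact while the
full sweep completes in well under a minute; larger networks exercise the
same code paths without changing what the comparison can show.

## Known limitations

* Reversal actions are modeled for irreversible model reactions only, and
  the brute-force oracle does not enumerate reversals (compare with
  `allow_reversal=False`).
* Reaction deletion or modification of existing gene-associated reactions
  is never proposed; the gap filler only adds and reverses.
* Cumulative steady-state imprecision *inside* the solver is not detectable
  from variable values alone; the package's defense is re-validation with
  an independently constructed LP, not introspection of the solver.
* Scoring is by reaction id, so semantically redundant database entries
  depress measured precision/recall even when the proposed chemistry is
  right; the near-miss report surfaces, but does not adjudicate, such cases.
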