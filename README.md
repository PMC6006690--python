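# gapfillkit

Parsimony-based gap filling of genome-scale metabolic models, with the
quality-control machinery that automated gap fillers need but rarely ship:
indicator-constraint auditing, minimality verification, an exact brute-force
oracle, and recall/precision benchmarking on networks with known ground
truth.

## The problem

Metabolic models derived from annotated genomes are incomplete: missing
enzyme annotations leave *gaps* in the reaction network, so flux balance
analysis (FBA) cannot route flux from the nutrients to all biomass
metabolites and the model fails to "grow". Gap filling proposes reactions
from a reference database to restore growth. This package implements the
cost-based mixed-integer formulation of that problem and — because MILP
solvers at finite tolerance can and do return wrong reaction sets — the
verification procedures that catch such errors.

## The model

Flux balance analysis: for stoichiometric matrix $S$ and flux vector
$v \ge 0$ (reversible reactions split into forward/backward columns),

$$\max\; v_{\text{biomass}} \quad \text{s.t.}\quad S v = 0,\; 0 \le v \le u,$$

with nutrient uptakes bounded, secretions free, and one lumped demand
consuming every biomass metabolite. A model grows when the optimum exceeds
a threshold (default $10^{-3}$ flux units).

Gap filling adds a Boolean $s_r$ per database candidate $r$, coupled to its
flux $f_r$ by indicator constraints

$$B_l\, s_r \;\le\; f_r \;\le\; B_u\, s_r,$$

so a selected candidate must carry at least the minimum active flux $B_l$
and a deselected one none. Reversing an existing irreversible reaction is a
costed action of the same form. The MILP minimizes total action cost under
the strict ordering

cost(reverse existing) < cost(insert in-taxon) < cost(insert out-of-taxon)

(defaults 1 < 2 < 4), subject to steady state and biomass flux above the
growth threshold. Solutions are *never trusted as returned*: every solve is
re-checked by an independent LP and audited for indicator violations
($s_r = 0$ with $|f_r| \ge B_l$) — the failure mode by which numerical
imprecision smuggles unneeded reactions into published solutions.

Predictions are scored against a reference set by exact reaction-id
matching: recall $= tp/(tp+fn)$, precision $= tp/(tp+fp)$.

## Worked example

A two-reaction glycolytic stub (`GLC -> G6P -> PYR`) that must synthesize
alanine it has no route to, and a three-candidate database in which `CAND1`
(`PYR -> ALA`, in-taxon), `CAND2` (`GLC -> ALA`, out-of-taxon) and `CAND3`
(`ALA -> PYR`, wrong direction) compete:

```sh
$ gapfillkit fba model.tsv condition.txt --producible
# status=optimal biomass_flux=0 grows=false
# producible=

$ gapfillkit gapfill model.tsv database.tsv condition.txt
CAND1	added	2
{
  "added": ["CAND1"],
  "reversed": [],
  "total_cost": 2.0,
  "status": "optimal",
  "objective_value": 10.0,
  "audit_clean": true,
  "unproducible": []
}
```

The gapped model cannot produce alanine (biomass flux 0). The gap filler
selects the in-taxon candidate `CAND1` at cost 2 — cheaper than the
out-of-taxon `CAND2` at cost 4 — and the completed model reaches biomass
flux 10, the glucose uptake bound. `audit_clean: true` records that the
MILP's selection variables and fluxes satisfy every indicator constraint.

Scoring a prediction `{CAND1, CAND2}` against a reference `{CAND1, CAND3}`:

```sh
$ gapfillkit evaluate predicted.txt reference.txt
{"tp": 1, "fp": 1, "fn": 1, "recall": 0.5, "precision": 0.5, ...}
```

The same operations are available as library functions
(`gapfillkit.gapfill`, `gapfillkit.evaluate_solution`, ...), and
`gapfillkit synth` generates whole benchmarks — a growing ground-truth
network, a gapped variant missing essential reactions, and a candidate
database with decoys — for controlled accuracy studies.

## Documentation

`docs/methods.md` describes the model, the synthetic benchmark generator,
numerical choices and known limitations.
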