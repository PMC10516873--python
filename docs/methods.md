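# Methods

This note documents the models, assumptions, parameters and numerical
choices behind `cyanoflux`, in the order a user meets them in the
pipeline.

## The constraint-based model

A metabolic network is represented by its stoichiometric matrix S
(metabolites × reactions), flux bounds LB/UB and a linear objective c.
Fluxes v are in mmol/gDW/h; a biomass pseudo-reaction's flux is the
specific growth rate (1/h).  The steady-state assumption S·v = 0 makes
no statement about metabolite pools, only about their net rates of
change.  Exchange (boundary) reactions are written `met ->`, so uptake is
a negative flux; a stated "uptake rate u" is installed as lower bound
−u on the exchange, which keeps secretion open and makes "uptake 0"
mean "no import" rather than "no flux".  A reaction is irreversible iff
LB ≥ 0.

Gene association is deliberately reduced to a per-reaction boolean: the
parsimonious penalty (below) needs to know which reactions represent
enzyme cost, nothing more.  Boundary, biomass and maintenance
pseudo-reactions are not gene-associated; everything else defaults to
gene-associated in the native dialect.  Full gene–protein–reaction rule
semantics are out of scope.

## Optimization layer

All problems are solved with the HiGHS LP/MILP solver through
scipy.optimize, with deterministic settings (presolve on, primal/dual
feasibility tolerances 1e−9, single-threaded), so repeated runs agree at
reporting precision.  Every optimal solution is verified on return:
steady-state residual ‖S·v‖∞ ≤ 1e−6 and bound violations ≤ 1e−6; a
violation raises instead of returning a silently bad flux state.

**FBA** maximizes (or minimizes) one flux or the model objective.  An
unbounded problem is reported as such, together with the support of an
unbounded ray, found by re-solving inside a large artificial box and
listing the fluxes that hit it.

**pFBA** first solves FBA, then fixes cᵀ·v = Z\* with an equality row
(relaxed to ±1e−6 relative only if the equality-fixed restoration fails
numerically) and minimizes Σ|vⱼ| over gene-associated reactions.  Each
penalized reaction is split as vⱼ = pⱼ − nⱼ with p, n ≥ 0, so the L1
objective is linear.  Degenerate LPs can still carry alternate optima at
the L1 minimum; individual fluxes are therefore compared downstream at
1e−4, while objective values and L1 norms are sharp.

**FVA** minimizes and maximizes each reaction flux subject to
cᵀ·v ≥ f·Z\*.  The default fraction is 0.95 (5% slack around the
best-known objective).  Per-reaction solver failures are recorded
per reaction rather than aborting the scan.  With the loopless switch,
each subproblem's solution is cycle-corrected before the reaction's flux
is read off.

**Loopless correction** follows the post-hoc strategy: boundary fluxes
and the objective value are fixed, every internal reaction is confined
to its current sign and magnitude, and total internal |v| is minimized.
This provably removes flux around internal cycles (which cannot change
any exchange) while leaving the physiology of the solution untouched,
and it needs no integer variables — the reason it is the default for
FVA-scale use.  A strict MILP loop-law mode (binary direction variables,
a potential vector orthogonal to the internal null space, big-M 1000) is
kept for small-instance validation; the test suite requires both modes
to agree on objective and exchanges.

**Two-step growth-coupled production**: maximize biomass (μ_max), pin
biomass ≥ f·μ_max (default f = 0.10, the carbon partitioning to biomass
reported feasible for hydrocarbon overproduction), then maximize the
product export by pFBA.  f = 0 recovers the plain product maximum; f = 1
the product maximum among growth-optimal states.  Product flux is
non-increasing in f — a property test covers the whole fraction grid.
pFBA runs before loop removal when both are requested.

**Phase planes** sweep one flux from zero to its maximum on an inclusive
grid (default 50 points) and report the attainable maximum of the other
flux at each point; infeasible grid points are flagged, never dropped.

## Flux-sum analysis and strain evaluation

The turnover (flux-sum) of metabolite i is
Φᵢ = ½·Σⱼ |Sᵢⱼ·vⱼ|; at steady state this equals both the producer-side
and the consumer-side sum, and the implementation checks this identity
network-wide.  A reaction sits on exactly one side per solution, decided
by the sign of Sᵢⱼ·vⱼ (threshold 1e−9 against numerical noise).
Flux-sums are per metabolite per compartment; the headline ATP/NADPH/NADH
numbers use the cytoplasmic species, the dominant pool, with an opt-in
aggregation across compartments.  Every reaction with nonzero cofactor
stoichiometry counts — including phosphotransfer reactions such as
adenylate kinase — because the definition is applied literally.  The
ATP/NADPH ratio is reported as undefined (not infinity) when the NADPH
flux-sum is zero.

Producer/consumer tables keep exact contributions for percent
bookkeeping but render contributions below 0.01 mmol/gDW/h as zero in
the display column, matching the convention that fluxes under the
reporting threshold are printed as zero.

Yields: productivity is the product export flux (growth rate for a
biomass objective); mass yield divides gram product by gram substrate
consumed (masses from elemental formulas unless supplied); c-mol yield
divides carbon exported in product by carbon imported through the
configured substrate exchanges.  The substrate basis follows the
scenario's carbon source — bicarbonate under the autotrophic preset,
glucose under the mixotrophic one — and is configurable.  Zero substrate
uptake yields a diagnostic, not an exception.

## Curation and pathway data

The edit set turning the iJN678 reconstruction into the analysis model,
and the four alkene pathway definitions, are version-controlled YAML
data, not code: supplementary reaction tables are data, and a user
holding the original tables must be able to correct the transcription
without touching the package.  Where the shipped transcription had to
make a judgment call — plastoquinone-pool ids for the NDH-2/ARTO
additions, the specific NAD(P)H dehydrogenase isoform constrained to
zero, the three-reaction glycine-cleavage replacement, exact alkene
pathway stoichiometries — the config file flags the entry as replaceable
and the loader treats new-metabolite declarations as create-if-absent,
so a corrected id binds to the existing pool.  Apply-time validation
reports id collisions and dangling references by name; every added
reaction is mass-checked where formulas permit, and imbalances are
logged (pseudo-reactions are legitimately unbalanced).

The ATP maintenance pseudo-reaction (ATP + H₂O → ADP + Pi + H) defaults
to a lower bound of zero under all scenarios: no numeric maintenance
coefficient is imposed, so any maintenance flux emerges from the
optimization.  Heterologous pathway reactions are gene-associated (they
are enzyme-catalyzed, so pFBA penalizes them); export pseudo-reactions
are not.  Trophic presets: autotrophic CO₂/HCO₃⁻/glucose uptake
0/3.7/0 mmol/gDW/h with the autotrophic biomass equation; mixotrophic
0/0/0.38 with the mixotrophic one; photon 45 mmol/gDW/h in both,
modelled as a single photon-exchange bound (not split across the two
photosystem absorption reactions — the simpler reading, and replaceable
via a custom condition).

## Synthetic benchmark networks

The generators exist so every stage is testable without downloading a
genome-scale model; they emulate structure, not scale.

* **Linear chains** have a one-dimensional flux polytope — the unique
  optimum makes FVA degeneracy checks sharp.
* **Internal-cycle models** attach a directed 3+-reaction cycle touching
  no exchange to a working chain: the canonical thermodynamically
  infeasible mode that loopless correction must zero without moving the
  objective.
* **Random feasible networks** plant a strictly positive flux vector in
  the null space of a sparse random S (the last column absorbs the
  residual) and draw bounds enclosing it, so feasibility is guaranteed
  by construction and every instance is reproducible from its integer
  seed.  They randomize the geometry that oracle-agreement tests (pFBA,
  FVA) sweep over.
* **The phototroph toy** is a frozen fixture (shipped as native-dialect
  files, never regenerated) emulating the energetic skeleton of a
  photoautotroph: a photon exchange capped at 45, linear electron flow
  producing 0.32 ATP and 0.25 NADPH per photon (output ratio 1.28, the
  published electron-chain stoichiometry), carbon fixation at
  3 ATP + 2 NADPH per CO₂, a biomass sink costing 1 ATP per fixed
  carbon, a product route costing 2 ATP + 1 NADPH per carbon, a
  flavodiiron-like NADPH valve, ATP maintenance, and an inactive
  NAD(H) couple.

  Its optima are hand-derived.  With photon flux L ≤ 45 and fixation
  F = μ + p: ATP requires 0.32·L ≥ 3F + μ + 2p = 4μ + 5p, NADPH
  requires 0.25·L ≥ 2F + p = 2μ + 3p.  The ATP line (μ/3.6 + p/2.88 = 1
  at L = 45) lies strictly inside the NADPH line over the whole
  quadrant, so ATP is binding everywhere: μ_max = 3.6, P_max = 2.88,
  and the frontier p(μ) = 2.88·(1 − μ/3.6) is exactly linear — hence
  the two-step product at f = 0.10 is 0.9·P_max = 2.592.  At either
  optimum L = 45 exactly, so Φ_ATP = 14.4, Φ_NADPH = 11.25 and
  ATP/NADPH = 1.28, with the NADPH surplus (4.05 at the biomass
  optimum) leaving through the valve.  These constants are frozen in
  `PHOTOTROPH_CLOSED_FORMS` and asserted exactly (1e−8) by the
  acceptance tests.

What passing these tests does **not** show: agreement with a real
genome-scale reconstruction (hundreds of coupled pathways, alternate
optima at scale, compartmentalized cofactor pools, biomass equations
with dozens of precursors) or with measured fluxes — the toys have no
regulation, no kinetics, and their cofactor structure is a two-resource
caricature.  They certify the algorithms, not the biology.

## Numerical choices and limitations

* Feasibility tolerance 1e−6 (reported), solver tolerances 1e−9; both
  configurable at the module level.
* Objective fixing in pFBA/loop removal uses equality rows rather than
  bound tightening — numerically robust across solvers.
* SBML bounds at magnitude ≥ 1e30 map to ±infinity; the native dialect
  stores floats via `repr`, so both dialects round-trip exactly.
* Ties between alternate optima are left to the deterministic solver;
  no lexicographic tie-break is imposed beyond the pFBA penalty.
* The strict loopless MILP is exponential in the worst case and
  intended for ≤ tens of reactions; the LP mode is the scalable path.
* Vertex-enumeration and epigraph oracles used in testing are
  exponential/duplicative by design and live in the test suite, not the
  package.
* The acceptance script sizes its problems for interactive use (20
  random 5×9 networks for pFBA agreement, 5 4×7 networks for FVA,
  cycles of length 3–5 for the loop law, a 13-point phase-plane grid) —
  chosen as the smallest sets that exercise every code path while
  keeping the whole run in seconds.
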