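# Methods

This note documents the models and procedures implemented in
`gemreduce`, the parameters that matter, the numerical choices, and what
the synthetic fixtures do and do not establish about real genome-scale
models.

## Thermodynamic model

The transformed Gibbs energy of reaction *i* at concentrations *x* is

    DrG'_i = sum_j n_ij * DfG'0_j + RT * sum_j n_ij * ln x_j

with R = 8.31e-3 kJ/K/mol and T = 298 K (RT = 2.47638 kJ/mol).  The
formation energies DfG'0 are *inputs* (a TSV table with a per-metabolite
estimation error and an explicit unknown marker with a reason); group
contribution estimation from molecular structures and protonation-state
computation are out of scope — a practitioner produces the table with
the established external tools and `gemreduce` consumes it.

Choices:

* **Protons and water** (formula `H` / `H2O`) are excluded from the
  concentration product.  Their activity is absorbed into the
  transformed formation energies at compartment pH; carrying ln x terms
  for them would double-count the pH dependence.
* **Estimation errors** widen the DrG' interval symmetrically by
  sum_j |n_ij| * err_j.  This is a hard widening; a chance-constrained
  treatment would be tighter but needs a distributional assumption the
  input table does not carry.
* **Directionality**: DrG'_max < 0 over the concentration box means
  forward-only, DrG'_min > 0 reverse-only; anything else stays
  bidirectional.  Reactions with any unknown participant impose no
  directionality constraint at all — they keep their flux bounds.  This
  is what makes partial thermodynamic coverage usable.
* **Pseudo-reactions** — boundary exchanges, demands/sinks, and the
  biomass reaction — carry no Gibbs constraint.  They are not chemical
  conversions; a reactants-only biomass "reaction" would otherwise have
  a structurally positive DrG' and falsely block growth.
* **Transmembrane reactions** use each participant's own compartment
  properties.  An electrochemical term per translocated charge is not
  applied by default (membrane potentials are carried in the compartment
  table but the coupling is off); for the toy scale of the test suite
  this term is immaterial, and it can be added where a study needs it.
* Default concentration box: 1e-11 to 0.1 M per compartment, overridable
  per compartment (the leukemia toy uses 1e-6 to 1e-2 M, a metabolomics-
  like window).

## The TFA MILP

Each reaction gets split non-negative fluxes (v = vF - vR), two binary
direction indicators, the couplings vF <= M*bF, vR <= M*bR,
bF + bR <= 1, and — if thermodynamically covered — a DrG' variable tied
to the log-concentration variables within the estimation-error band and
sign-coupled to the binaries (DrG' - M + M*bF <= 0 and the mirror
constraint).  Binaries exist for *all* reactions, covered or not,
because the minimal-medium and minimal-subnetwork searches use them as
activity indicators.

* Big-M values: 1000 mmol/gDW/h for fluxes, 1000 kJ/mol for Gibbs
  energies, both configurable; the builder refuses a model whose bounds
  or reachable |DrG'| exceed them (a silent undersized big-M would relax
  constraints invisibly).  DrG' variables are additionally bounded by
  their own extremized interval, which tightens the LP relaxation.
* Solver: HiGHS through scipy (`scipy.optimize.milp`), relative MIP gap
  0 — all cardinality objectives here are integer-valued, so optimality
  is exact.  Variables are created in sorted-reaction-id order, making
  the matrix, and hence the solver trajectory, identical across runs.
* Infeasibility is a *result* (a status), never an exception, because
  the exploration paths (variability analysis, knockouts, enumeration)
  legitimately hit infeasible instances.

## Minimal-medium search (iMM)

Per boundary reaction k a binary z_k with bF_k + bR_k + C*z_k <= C
forces the boundary closed when z_k = 1; the objective maximizes
sum z_k under v_biomass >= mu_min.  C = n_b + 1: any C > 1 makes the
coupling exact, and a small C conditions the MILP better than an
arbitrary large constant.  Both uptakes and secretions count; a config
switch restricts the count to uptake-capable boundaries.  The growth
requirement is an absolute mu_min (h^-1) rather than a fraction of the
maximum — the caller can compute the maximum first if a fractional
policy is wanted.  The biomass drain itself never counts as a boundary.
Alternative media of the same optimal size are enumerated by integer
cuts (sum_{k in A} z_k >= 1 over the found active set A), which at fixed
optimal cardinality excludes exactly the found set.

## Core network

The starting subsystems are label-defined reaction sets.  Two growth
moves build the core:

* **Intra-expansion** adds any reaction (whatever its own label) whose
  non-cofactor participants all belong to a single starting subsystem's
  metabolite set.  Subsystem labels in large reconstructions are noisy;
  this recovers reactions that operate inside a subsystem but are filed
  elsewhere.  Transports never qualify, because extracellular species
  are never subsystem members.
* **Degree-D connection** runs a directed search over the
  metabolite-reaction graph and adds every path of at most D reactions
  between two subsystem metabolites whose intermediates are outside all
  subsystems.  Distance counts *reactions*: a k-path has k reactions and
  k-1 intermediate metabolites, all of which join the core.  Cofactor
  pairs (default list: ATP/ADP/AMP, NAD(P)(H), CoA, protons, water,
  Pi/PPi, CO2, O2, matched by id base name and user-overridable) and the
  extracellular compartment are excluded as carriers — connecting the
  medium is the next stage's job, and cofactor links would connect
  everything to everything.
* The pairwise connectivity matrix counts distinct connecting reactions
  per unordered subsystem pair (undirected counting; the same-subsystem
  diagonal is reported too).

## Medium connection and biosynthetic lumping

Both searches instantiate the same engine: binaries z_i over a *counted*
set of candidate reactions, bF + bR + z <= 1, a flux forcing (uptake of
the target medium metabolite >= c, or a BBB demand >= c), objective
max sum z.  Smin = |counted| - optimum; integer cuts enumerate every
alternative active set of size Smin.

* c defaults to 1e-3 mmol/gDW/h — three orders of magnitude above the
  solver feasibility tolerance (1e-9 scale), small enough not to
  distort the witness fluxes.
* **Counting.**  Boundary reactions are exempt from the count (and the
  forced uptake exchange in particular): subnetwork size measures
  network reactions — transports and conversions — not the environment's
  side of the exchange.  This makes a target with a direct transporter
  to the core have Smin = 1.
* **Blocking** (medium connection): non-core reactions among purely
  extracellular metabolites, and the boundary/transport reactions of
  extracellular metabolites that are neither medium nor core, are
  clamped to zero during the search, so a subnetwork must actually reach
  the core rather than drift through unrelated exchanges.
* **Alternative identity** is the set of active counted reactions, not
  the flux witness: two witnesses over the same set are one alternative.
* Thermodynamic constraints stay active during the search by default;
  a switch runs the search on stoichiometry alone.  The planted test
  fixtures use a neutral thermodynamic table (all DfG'0 = 0, errors 0)
  so that the MILP and the LP-based brute-force oracle see the same
  feasible sets.
* At the lumping stage, the medium-connection reactions found earlier
  are treated as core: usable and not counted.

**Lumping.**  For each minimal subnetwork the witness weights come from
an LP re-solve with the active set fixed, the BBB demand pinned to 1,
and total absolute flux minimized (a parsimonious, reproducible
witness).  Weights are reconstructed as exact rationals (denominator cap
1e4) and the net reaction sum_i w_i * S_i is formed in Fraction
arithmetic; metabolites internal to the subnetwork must cancel to
exactly zero and the net reaction must inherit elemental balance — if
reconstruction or verification fails the float weights are kept and the
lump is flagged inexact.  Lumps are normalized to BBB coefficient 1 and
deduplicated by exact net stoichiometry (different subnetworks can
collapse to the same net reaction).  Stoichiometric coefficients
throughout the package are Fractions (decimal inputs snapped at
denominator 1e6) precisely so this summation is exact.

**Lump gene rules** are the conjunction (AND) of the constituent
reactions' rules: a lumped pathway is available exactly when every one
of its reactions is available.  This is what preserves gene essentiality
through the reduction — knocking out a gene that disables any
constituent disables the lump.  (A union/OR semantics would silently
lose parent-essential genes; an OR override exists for users who want an
optimistic lump.)  Two reduction flavors exist: `one-per-BBB` (first
minimal subnetwork per BBB) and `Smin` (all unique lumps of minimal
size).

## Reduced-model assembly and validation

The reduction contains: core reactions, medium-connection reactions,
the biomass reaction, the lumped reactions, and the boundary reactions
of every metabolite that survived (with their curated bounds).  Assembly
fails loudly when a BBB that needs a lump has none.  The statistics
block (metabolite/enzymatic/boundary/transport/lumped counts, genes,
thermodynamic coverage) is recomputed from the assembled model, never
carried over.

Validation battery:

* **Metabolic tasks** — a task closes all uptakes, opens its declared
  inputs, demands its outputs, applies overrides, and passes iff the TFA
  problem stays feasible.  A task referencing an entity absent from the
  model fails with category `missing-entity`; in reductions the typical
  cause is a species hidden inside a lumped reaction, and re-exposing
  the explicit subnetwork recovers the task.
* **Gene essentiality** — a knockout disables every reaction whose
  boolean gene rule evaluates false (rule evaluation via COBRApy's GPR);
  essential means maximal growth < 1e-6 h^-1 afterwards (a cutoff well
  above solver tolerance).  Reactions without a rule are never disabled.
  The consistency property checked on every fixture: genes present in
  the reduction and essential in the parent are essential in the
  reduction.  The converse direction is *not* claimed — removing
  parallel routes can create reduction-only essential genes, and the
  fixtures exhibit this.
* **TVA comparison** — ranges for the common reactions under identical
  physiology, sorted by absolute range change; relative change is
  (parent width - reduced width) / max(parent width, 1e-9).
* **Minimal active network** — minimize sum(bF + bR) under a demand on a
  target metabolite; here boundaries *do* count (the question is how
  many reactions must run, environment included), and the added demand
  itself does not.

## Medium curation

Applying a medium closes the uptake direction of every non-medium
exchange and caps medium uptakes.  Two rule families ship as defaults:
close exchanges of species with no transport reaction (an exchange the
cell cannot actually use), and block transports whose cargo contains
phosphorus or matches CoA/ACP name patterns (phosphorylated and
carrier-bound species do not cross membranes freely).  The forbidden
classes are named; the matching rule (formula element / name regex) is a
package choice and fully configurable.  Curation only ever tightens
bounds, never adds or removes reactions, and every closure is logged
with its triggering rule.

## Synthetic fixtures and what the tests show

Network structure in the fixtures is *constructed*, not sampled: the
seed only shuffles insertion order (all algorithms iterate in sorted-id
order, so results are seed-invariant and serialized fixtures are
byte-identical per seed).  Each fixture plants, by construction: the
intra-expansion reaction, degree-1 and degree-2 bridges, a medium
metabolite whose minimal connection has a known size and alternative
count, a BBB whose minimal biosynthesis subnetwork includes a cofactor
regeneration cycle, three alternative carbon sources giving a known
minimal-medium size and count, and gene rules of all three shapes
(sole-path, isozyme pair, obligate complex).  At generation time every
planted number is re-derived by exhaustive brute-force oracles
(LP-feasibility over all subsets, networkx path enumeration, exhaustive
knockouts); a fixture that contradicts its plant is never emitted.  The
suite of ten fixtures varies chain lengths (1-4) and alternative counts
(1-3), keeping the candidate sets within the brute-force cap
(<= 14 candidates).

Problem sizes: fixtures have <= 30 reactions, the full test suite and
the acceptance script each run in well under a minute on one CPU.  These
sizes were chosen so the *exhaustive* oracles remain the arbiter; the
MILPs themselves scale far beyond them.

What passing does **not** show: fixture thermodynamics is mostly
neutral (directionality checks use dedicated planted-bottleneck toys),
metabolite formulas are stylized single-element strings, there are no
multi-compartment intracellular topologies, and no fixture approaches
the combinatorics of a real human reconstruction — runtime and
degeneracy behavior at that scale (thousands of alternative optima,
solver tolerance interactions) are not exercised here.

## Known limitations

* The electrochemical membrane-potential term is available in the data
  model but not applied in DrG' by default.
* Alternative subnetworks are enumerated, not ranked; thermodynamic
  favorability ranking of alternatives is out of scope.
* Metabolite annotations are pass-through strings; no identifier
  reconciliation against external namespaces.
* The task engine ships with a toy task set; production task content is
  an input file.
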