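# gemreduce

Thermodynamically curated reduction of genome-scale metabolic models
(GEMs).

Genome-scale reconstructions of human metabolism contain thousands of
reactions, most of which are irrelevant to any one physiological
question, and their size makes thermodynamic curation, data integration
and interpretation hard. `gemreduce` builds **reduced models** around a
chosen set of subsystems while guaranteeing that the reduction stays
consistent with the parent model: it can still consume its medium,
synthesize its biomass, and satisfy the laws of thermodynamics.

## What it does

Given a GEM (SBML or a documented JSON dialect), a table of standard
transformed Gibbs formation energies ΔfG'° with estimation errors, a
medium definition, and a list of starting subsystems, the pipeline runs
six stages:

1. **Thermodynamic curation** — each covered reaction *i* gets a Gibbs
   energy constraint tied to metabolite log-concentrations,

   ΔrG'ᵢ = Σⱼ nᵢⱼ ΔfG'°ⱼ + RT Σⱼ nᵢⱼ ln xⱼ    (R = 8.31·10⁻³ kJ/K/mol, T = 298 K)

   with concentrations bounded per compartment (default 10 pM – 0.1 M).
   Extremizing over the concentration box, widened by Σ|nᵢⱼ|·errⱼ,
   classifies reactions as forward-only, reverse-only or bidirectional.
2. **TFA / TVA** — flux balance as a MILP: split fluxes v = vF − vR,
   direction binaries bF, bR with big-M couplings, and sign consistency
   bF = 1 ⇒ ΔrG' ≤ 0 (and symmetrically).  Thermodynamic flux
   variability analysis (TVA) is the per-reaction min/max under this
   constraint set; it is always contained in the plain FVA range.
3. **Minimal medium (iMM)** — a binary z per boundary reaction with
   bF + bR + C·z ≤ C maximizes the number of inactive boundaries under a
   growth requirement; integer cuts enumerate all alternative minimal
   media.
4. **Core network** — the starting subsystems are intra-expanded
   (reactions whose non-cofactor participants all lie in one subsystem)
   and pairwise-connected by every path of at most D reactions between
   subsystem metabolites, excluding cofactor pairs and the extracellular
   compartment as carriers.
5. **Medium connection** — for each extracellular medium metabolite, a
   MILP (bF + bR + z ≤ 1 per non-core reaction, forced uptake ≥ c,
   maximize Σz) finds the **minimal subnetwork** of non-core reactions
   connecting it to the core — including whatever balances the
   by-products — and enumerates all alternatives of minimal size Smin.
6. **Biosynthetic lumping and validation** — the same search produces,
   for every biomass building block (BBB) the core cannot supply, its
   minimal biosynthesis subnetworks; each is collapsed into one **lumped
   reaction** by flux-weighted summation with exact rational arithmetic
   (intermediates cancel to exactly zero; elemental balance is
   preserved).  The assembled reduction is validated by metabolic-task
   checks, single-gene knockout essentiality (parent-essential genes
   must stay essential), and TVA comparison against the parent.

Every MILP search in the package is certified on planted synthetic
fixtures whose ground truth is re-derived by exhaustive brute-force
enumeration (all subsets of candidate reactions, LP feasibility per
subset).

## Worked example

Generate the built-in planted toy model (two subsystems, a planted
degree-1 bridge, a 2-step medium chain with 2 alternative routes, and a
biomass building block needing a 3-reaction subnetwork with a cofactor
regeneration cycle), then reduce it:

```sh
gemreduce fixtures --seed 1 --kind planted --out toy
cat > medium.yaml <<EOF
uptakes: {u1_e: 10.0, n_e: 10.0, med_e: 10.0, wn_e: 0.0}
EOF
cat > cfg.yaml <<EOF
model: toy.json
thermo: toy_thermo.tsv
medium: medium.yaml
subsystems: [UPPER, LOWER]
degree: 1
flavor: Smin
exclude_targets: [wn_e]
EOF
gemreduce run cfg.yaml --out reduction
```

which prints

```
reduced model written to reduction: 13 metabolites, 19 reactions (1 lumped)
```

`reduction/statistics.tsv` breaks the 19 reactions down (8 enzymatic,
5 boundary, 5 transport, 1 lumped; 17 genes; 100% of metabolites with
Gibbs energies), and `reduction/lumped_reactions.tsv` shows the lump:

```
bbb	lump	size	reactions	equation
p_c	LMP_p_c_0	3	R_P1,R_PF0,R_W	l2_c --> p_c
```

— the 3-reaction subnetwork (two conversions plus the cofactor
regeneration) collapsed to the net conversion `l2_c --> p_c`; the
cofactor pair and the chain intermediate cancelled exactly.  The
minimal-medium search on the same model:

```sh
gemreduce imm toy.json --growth-lb 0.1 --out media.tsv
```

```
3 minimal media of size 2
```

with the three alternatives (one of three carbon sources, plus the sole
nitrogen source) listed in `media.tsv`.  Example configurations for a
human-model run — cancer-relevant core subsystems, compartment
properties, leukemia physiology (growth cap 0.035 h⁻¹, O₂ uptake
≤ 2 mmol·gDW⁻¹·h⁻¹, ATP maintenance ≥ 1.07 mmol·gDW⁻¹·h⁻¹), and a
toy task set — are in `examples/`.

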