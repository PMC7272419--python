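# Example metabolic-task set for the planted toy model.  Each task opens
# the listed inputs (every other uptake closed), demands the outputs, and
# passes when the thermodynamically constrained problem stays feasible.
- id: uptake-carbon
  description: primary carbon source can be consumed
  inputs: [{metabolite: u1_e, max_rate: 10}]
  outputs: [{metabolite: sec_e, min_rate: 1.0e-3}]
- id: uptake-medium-metabolite
  description: the distal medium metabolite can be consumed
  inputs: [{metabolite: med_e, max_rate: 10}]
  outputs: [{metabolite: sec_e, min_rate: 1.0e-3}]
- id: uptake-nitrogen
  description: nitrogen source can be consumed and its waste secreted
  inputs: [{metabolite: n_e, max_rate: 10}]
  outputs: [{metabolite: wn_e, min_rate: 1.0e-3}]
- id: lower-subsystem-product
  description: the end product of the lower subsystem is reachable
  inputs: [{metabolite: u1_e, max_rate: 10}]
  outputs: [{metabolite: l2_c, min_rate: 1.0e-3}]
- id: biosynthetic-product
  description: the lumped biomass building block is reachable
  inputs: [{metabolite: u1_e, max_rate: 10}]
  outputs: [{metabolite: p_c, min_rate: 1.0e-3}]
- id: growth
  description: biomass can be synthesized from the full medium
  inputs:
    - {metabolite: u1_e, max_rate: 10}
    - {metabolite: n_e, max_rate: 10}
  overrides: {BIOMASS: [1.0e-3, 1000.0]}
- id: growth-on-alternative-chain
  description: biomass using the distal medium metabolite as sole carbon
  inputs:
    - {metabolite: med_e, max_rate: 10}
    - {metabolite: n_e, max_rate: 10}
  overrides: {BIOMASS: [1.0e-3, 1000.0]}
- id: biosynthetic-intermediate
  description: fails on reductions that hide the intermediate in a lump
  inputs: [{metabolite: u1_e, max_rate: 10}]
  outputs: [{metabolite: q1_c, min_rate: 1.0e-3}]
- id: bridge-intermediate
  description: fails on degree-1 reductions (needs the degree-2 bridge)
  inputs: [{metabolite: u1_e, max_rate: 10}]
  outputs: [{metabolite: x1_c, min_rate: 1.0e-3}]
- id: secretion-only-check
  description: nothing can be made from a closed medium
  outputs: [{metabolite: sec_e, min_rate: 1.0e-3}]
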