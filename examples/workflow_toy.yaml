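# Full-workflow configuration for the planted toy model.
# Generate the inputs first:
#   gemreduce fixtures --seed 1 --kind planted --out examples/toy
# then:
#   gemreduce run examples/workflow_toy.yaml --out toy_reduction
model: examples/toy.json
thermo: examples/toy_thermo.tsv
medium: examples/medium_toy.yaml
subsystems: [UPPER, LOWER]
degree: 1
c: 1.0e-3
flavor: Smin
exclude_targets: [wn_e]
out: toy_reduction
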