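# Example starting-subsystem selection for studying cancer metabolism in
# a human genome-scale model: central carbon pathways plus subsystems
# reported as deregulated in cancer cells.  Subsystem names follow the
# labels used in the human reconstructions.
subsystems:
  - Glycolysis/gluconeogenesis
  - Pentose phosphate pathway
  - Citric acid cycle
  - Oxidative phosphorylation
  - Glutamate metabolism
  - Glycine, serine, alanine and threonine metabolism
  - Urea cycle
  - ROS detoxification
degree: 1
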