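# Medium for the planted toy model: carbon (u1), nitrogen (n), the
# distal medium metabolite (med), and the nitrogen-waste species (wn,
# secretion only).
uptakes:
  u1_e: 10.0
  n_e: 10.0
  med_e: 10.0
  wn_e: 0.0
closed_secretions: []
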