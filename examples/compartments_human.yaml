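# Compartment properties for a human-cell model: pH, ionic strength (M),
# membrane potential vs cytosol (mV), and the generic concentration
# window of 10 pM to 0.1 M used when no metabolomics is available.
c:  {pH: 7.00, ionic_strength: 0.15, membrane_potential: 0.0,   conc_lb: 1.0e-11, conc_ub: 0.1}
e:  {pH: 7.40, ionic_strength: 0.15, membrane_potential: 30.0,  conc_lb: 1.0e-11, conc_ub: 0.1}
m:  {pH: 8.00, ionic_strength: 0.15, membrane_potential: -150.0, conc_lb: 1.0e-11, conc_ub: 0.1}
x:  {pH: 7.00, ionic_strength: 0.15, membrane_potential: 0.0,   conc_lb: 1.0e-11, conc_ub: 0.1}
r:  {pH: 7.20, ionic_strength: 0.15, membrane_potential: 0.0,   conc_lb: 1.0e-11, conc_ub: 0.1}
g:  {pH: 6.35, ionic_strength: 0.15, membrane_potential: 0.0,   conc_lb: 1.0e-11, conc_ub: 0.1}
l:  {pH: 5.50, ionic_strength: 0.15, membrane_potential: 19.0,  conc_lb: 1.0e-11, conc_ub: 0.1}
n:  {pH: 7.20, ionic_strength: 0.15, membrane_potential: 0.0,   conc_lb: 1.0e-11, conc_ub: 0.1}
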