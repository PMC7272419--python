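# Leukemia physiology: growth capped at the reported doubling rate,
# oxygen uptake and ATP maintenance from literature values.
growth_cap: 0.035            # 1/h
oxygen_uptake_cap: 2.0       # mmol/gDW/h
atp_maintenance_floor: 1.07  # mmol/gDW/h
oxygen_exchange: EX_o2_e
atp_maintenance_rxn: ATPM
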