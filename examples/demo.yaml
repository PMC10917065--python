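# Small demo study: four serum cohorts, planted IgA reactivity with
# matched SNA sialylation on CT001, a trickle of polyspecific samples.
seed: 7
groups:
  - {label: PDAC, n: 8, specimen: serum}
  - {label: CP, n: 5, specimen: serum}
  - {label: DYS, n: 5, specimen: serum}
  - {label: LTBI, n: 8, specimen: serum}
channels: [IgG, IgA, IgA1, IgA2, SNA, RCA]
panel: {n_ct: 40, n_ta: 10}
psa_fraction: 0.05
effects:
  planted_effects:
    - {group: PDAC, channel: IgA, antigen_id: CT001, log2_fc: 1.0, penetrance: 0.8}
    - {group: PDAC, channel: IgA, antigen_id: CT002, log2_fc: 1.0, penetrance: 0.8}
    - {group: PDAC, channel: SNA, antigen_id: CT001, log2_fc: 2.0}
panel_sizes: [2, 3]
top_m: 8
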