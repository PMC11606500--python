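# Default receptor-level annotation rules (first matching priority wins).
- label: MAIT
  priority: 0
  required_v: [TRAV1-2]
  required_j: [TRAJ33, TRAJ20, TRAJ12]
- label: gamma_delta
  priority: 1
  required_locus: [TRG, TRD]
- label: CD1bc_candidate
  priority: 2
  required_pairing: [TRAV13-2, TRBV4-1]
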