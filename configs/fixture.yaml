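# Small end-to-end fixture: 2 chromosomes, 5,000 markers, 120 lines.
seed: 1
simulate:
  n_lines: 120
  n_chrom: 2
  chrom_length_bp: 30000000
  n_markers: 5000
  n_environments: 2
  planted_qtls:
    - {trait: trait1, chrom: 1, pos_bp: 6000000, var_fraction: 0.25}
    - {trait: trait1, chrom: 2, pos_bp: 22500000, var_fraction: 0.25}
ld:
  n_pairs: 15000
  n_sets: 3
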