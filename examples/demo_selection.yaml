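# Demo reselection on the packaged 85-nt reference: doped at 21% per
# position, enrichment requires forming all four Stem 1 pairs plus at least
# seven of the eight Stem 3 pairs.
rate: 0.21
pool_size: 20000
rounds: 3
reads_per_round: 5000
seed: 11
stems:
  - name: Stem1
    min_pairs: 4
  - name: Stem3
    min_pairs: 7
active_level: 1.0
background_level: 0.01
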