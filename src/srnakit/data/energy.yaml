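# Default nearest-neighbor-style energy parameters (kcal/mol) for the
# single-stem-loop folding model. A stack of two adjacent base pairs
# contributes the mean of the two per-pair energies; unpaired loops are
# penalized as loop_a + loop_b * ln(L / 4), floored at 0.
pair_energies:
  GC: -3.3
  AU: -1.1
  GU: -0.5
loop_a: 5.5
loop_b: 2.0
min_loop: 3
max_interior: 3
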