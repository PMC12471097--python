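# Ionizable-group pKa values for Henderson-Hasselbalch net-charge curves.
#
# Two sets are shipped because the isoelectric-point column and the pH-7
# net-charge column of the reference characterization were produced by two
# different calculators whose His pKa differs:
#   pi     - EMBOSS-style values; reproduces every printed pI
#            (neutral baseline 6.10 = midpoint of the terminal pKas).
#   charge - identical except His 6.0; reproduces the printed pH-7 charges
#            (QH +0.1, CF -0.1).
# Polarity: nterm/H/K/R are bases (charged below their pKa),
# cterm/C/D/E/Y are acids (charged above).
pka_sets:
  pi:
    nterm: 8.6
    cterm: 3.6
    C: 8.5
    D: 3.9
    E: 4.1
    H: 6.5
    K: 10.8
    R: 12.5
    Y: 10.1
  charge:
    nterm: 8.6
    cterm: 3.6
    C: 8.5
    D: 3.9
    E: 4.1
    H: 6.0
    K: 10.8
    R: 12.5
    Y: 10.1
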