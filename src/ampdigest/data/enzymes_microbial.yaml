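# Proteases of gastrointestinal microorganisms used for the resistance screen.
#
# Oligopeptidase F (lactococcal M3-family oligoendopeptidase) does not act on
# very short substrates; the length floor of 4 leaves every di/tripeptide
# intact, which is the behaviour observed across the whole resistance
# snapshot.  Its P1 set only matters for substrates at or above the floor.
#
# Proteinase P1 (lactocepin, EC 3.4.21.96) has combinatorial subsite
# preferences that a P1-only rule cannot capture (G|L is cleaved while G|F
# and G|K are not), so it is encoded as an explicit table of cleaved
# (P1, P1') pairs; pairs not listed are resistant.
enzymes:
  oligopeptidase_f:
    ec_number: 3.4.24.-
    p1: [K, R, A, F, L, M]
    min_substrate_length: 4
  proteinase_p1:
    ec_number: 3.4.21.96
    pairs: [PG, GL, IL, VF, PL, PK, PW, PF, QH, QL]
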