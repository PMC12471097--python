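# Methods

## Digestion model

Proteolysis is modeled as simultaneous, exhaustive bond cleavage: a
peptide bond `x|y` (bond *i* joins residues *i* and *i+1*, 0-based) is cut
when residue `x` is in an enzyme's P1 set or the ordered pair `(x, y)` is
in its cleaved-pair table, and `y` is not in its P1′ exclusion set.  Cut
sites from all active enzymes are unioned and applied in one pass; the
fragments are the maximal runs between cuts.  This is the convention of
the standard "action of enzymes" in-silico tools: no kinetics, no missed
cleavages, no pH dependence.  The model is a fixed point after one pass —
re-digesting any released fragment changes nothing — which the test suite
asserts, along with equivalence to an independent per-bond brute-force
oracle on seeded random peptides.

Enzyme specificity lives in configuration (`data/enzymes_gi.yaml`), not
code.  The shipped gastrointestinal set is

| enzyme | P1 set | note |
|---|---|---|
| pepsin (pH 1.3) | F, L | the classical low-pH specificity |
| trypsin | K, R | |
| chymotrypsin | F, Y, W, L, M, N, H | calibrated, see below |

Two deliberate choices depart from textbook protease tables:

* **Chymotrypsin is broader than F/Y/W.**  The high-specificity set
  cannot release several of the bioactive fragments observed in the
  reference digestion snapshot (TW, IY and TF need N↓X cleavage; QH and
  IM need H↓X).  The shipped set is calibrated so that every observed
  (fragment, source) release is reproduced from the 57-peptide panel;
  because it is data-driven it is stored in the YAML asset and can be
  replaced per run (`--enzymes`).
* **No P1′ proline exclusion by default.**  The observed releases require
  Y↓P and L↓P cleavage (the PK and GL fragments), so the classical
  "no cut before proline" restriction is off; it remains available via
  `p1prime_exclusions` for users modeling other digests.

## Microbial-resistance screen

Released di/tripeptides are re-digested separately with two proteases of
small-intestine microorganisms.  Oligopeptidase F is modeled as inactive
on substrates shorter than 4 residues (every di/tripeptide in the
reference screen survives it); the floor is configurable and its P1 set
only matters at or above it.  Proteinase P1 (lactocepin) has
combinatorial subsite preferences that no P1-only rule captures — G↓L is
cut while G↓F and G↓K are not — so it is encoded as an explicit table of
ten cleaved (P1, P1′) pairs derived from the observed outcomes:
PG, GL, IL, VF, PL, PK, PW, PF, QH, QL.  Unlisted pairs default to
resistant.  A fragment is *resistant* when both enzymes return it intact.
The classifier is definitionally a `digest()` call per enzyme; a test
asserts that equality.

## Physicochemical descriptors

All descriptors are computed on unrounded values; interpretation flags
are applied before display rounding.

* **GRAVY** — mean Kyte–Doolittle hydropathy (scale from Biopython's
  ProtParam data).  Dimensionless, range [−4.5, 4.5].
* **Aliphatic index** — Ikai's `100·(f_A + 2.9·f_V + 3.9·(f_I + f_L))`
  on mole fractions; > 100 is read as thermostability.  (The alternative
  reading tying thermostability to instability index > 100 contradicts
  the standard definition and the observed classification — the eight
  peptides called thermostable are exactly those with aliphatic
  index > 100 — so the aliphatic-index interpretation is implemented.)
* **Boman index** — mean per-residue transfer free energy (kcal/mol),
  stored hydrophilic-positive (negated Radzicka–Wolfenden values;
  proline, unmeasured, is 0) so the index is a plain mean.  Values above
  2.48 kcal/mol flag high protein-/membrane-binding potential.  Display
  truncates toward zero at 2 decimals, matching the reference
  calculator's convention (diagnosed from half-cent cases such as
  AR 6.555 → 6.55); the underlying value is untouched.
* **Instability index** — Guruprasad's `(10/L)·Σ DIWV(xᵢ, xᵢ₊₁)` with
  the published 20×20 dipeptide weight matrix (Biopython's ProtParam
  data; unlisted pairs default to 1.0).  Undefined for single residues —
  length 1 raises rather than guessing.  > 40 is read as unstable
  in vitro.  Cross-checked against Biopython's own implementation as an
  independent oracle.
* **Net charge** — Henderson–Hasselbalch sum over the N-terminus
  (base), C-terminus (acid) and ionizable side chains (C, D, E, Y acids;
  H, K, R bases): bases contribute `+1/(1+10^(pH−pKa))`, acids
  `−1/(1+10^(pKa−pH))`.
* **Theoretical pI** — the unique root of the charge curve on [0, 14].
  Every term is strictly decreasing in pH, so the root exists (the
  N-terminal base dominates at pH 0, the C-terminal acid at pH 14) and
  is unique; it is found with a bracketing root search (Brent's method,
  `xtol = 1e−9`), which meets the same contract as plain bisection with
  fewer evaluations.  Reported to 2 decimals; tests assert
  `|charge(pI)| < 1e−4`.
* **Water solubility** — `good` iff the peptide contains at least one
  charged side chain (D, E, K, R, H), else `poor`.  This simple rule
  reproduces the reference good/poor column exactly; the proprietary
  heuristic of the upstream web calculator is not reverse-engineered
  further.

### pKa sets

Two EMBOSS-style sets ship (`data/pka_sets.yaml`): N-term 8.6,
C-term 3.6, C 8.5, D 3.9, E 4.1, K 10.8, R 12.5, Y 10.1, with **His 6.5**
for the pI column and **His 6.0** for the pH-7 charge column.  The split
exists because the two reference columns came from different calculators:
the 6.5 set reproduces every printed pI (neutral baseline
(8.6+3.6)/2 = 6.10, AR 10.55, EK/ER 6.41, QH 7.55, CF 5.92, IY 6.09), the
6.0 set the printed charges (QH +0.1, CF −0.1).

### Known data inconsistencies

The reference characterization's GK row (charge 0, pI 6.70, instability
−3745) is inconsistent with the method that produces every other row,
which gives +1, 9.70 and −37.45 (PK and SK, with the same ionizable
groups, print +1/9.70; −3745 is plausibly a dropped decimal point).  The
package computes the consistent values; the tests exclude exactly these
three GK cells.  Similarly, the activity snapshot cites one source
accession (AP01328) that the printed 57-record panel does not contain;
the annotation keeps the citation as printed, and the pipeline simply
cannot (and does not claim to) release fragments from an absent sequence.

## Synthetic data generator

`random_peptides` draws lengths uniformly from a range (default 2–60,
spanning di-peptides to the longest panel members) and residues i.i.d.
from configurable composition weights (default uniform over the 20
canonical residues), via one `numpy` Generator seeded explicitly — no
global random state.  `embed_motif` appends a motif behind a flank
residue drawn from the rule set's P1 specificity so the digestion
provably releases it, and refuses motifs the rule set would cut
internally.  The generator emulates sequence-level statistics only: it
makes no attempt at AMP secondary structure, cysteine pairing or
cyclotide topology, so passing property tests demonstrate the engine's
combinatorial correctness, not biological realism of random hosts.

## Problem sizes and determinism

The shipped analyses are desk-scale: 57 peptides of length 8–47, 47
released di/tripeptides, 22 bioactive ones.  Property suites run on
1,000 seeded synthetic peptides (digestion identity and oracle
equivalence; charge monotonicity and pI residual) and 200 planted-motif
constructs — sizes at which the checked invariants are exercised across
the whole length range while the suite stays interactive.  Reruns of the
pipeline with a fixed configuration are byte-identical; run metadata
records asset checksums and the active rule set.

## Limitations

* Cleavage is binary and context-free beyond (P1, P1′); no kinetics,
  no partial digestion, no pH dependence.
* Activity annotation is a lookup of known short peptides, not a
  predictor; unseen fragments are reported unannotated, never scored.
* The lactocepin pair table encodes observed outcomes for the 22
  screened fragments; extrapolation to unlisted pairs (default:
  resistant) is an assumption.
* No structure, disulfide connectivity, aggregation or half-life
  modeling.
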