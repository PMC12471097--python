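"""Seeded synthetic peptide generation for end-to-end testing.

Random peptides stand in for database-derived oligopeptides so that every
pipeline stage is exercisable without external data: lengths are uniform
over a range, residues i.i.d. under a configurable composition, and known
bioactive motifs can be planted so that a given rule set is guaranteed to
release them.  All randomness flows through one explicit integer seed —
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cleavage import EnzymeRule, digest, find_cleavage_sites
from .records import CANONICAL_RESIDUES, PeptideRecord, validate_sequence

_ALPHABET = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic peptide source.

    ``composition`` maps residues to nonnegative sampling weights
    (missing residues get weight 0; uniform when omitted).
    """

    n: int = 10
    length_range: tuple[int, int] = (2, 60)
    composition: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def weights(self) -> np.ndarray:
        if not self.composition:
            w = np.ones(len(_ALPHABET))
        else:
            for res, wt in self.composition.items():
                if res not in CANONICAL_RESIDUES:
                    raise ValueError(f"unknown residue {res!r} in composition")
                if wt < 0:
                    raise ValueError("composition weights must be nonnegative")
            w = np.array([self.composition.get(a, 0.0) for a in _ALPHABET])
        if w.sum() <= 0:
            raise ValueError("composition weights sum to zero")
        return w / w.sum()

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


def random_peptides(config: GeneratorConfig) -> list[PeptideRecord]:
    """Draw ``config.n`` random peptides; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    probs = config.weights()
    lo, hi = config.length_range
    records = []
    for i in range(config.n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_ALPHABET, size=length, p=probs))
        records.append(PeptideRecord(f"SYN{i:05d}", "synthetic", "", seq))
    return records


class MotifError(ValueError):
    """The motif cannot be released intact under the given rule set."""


def _cut_before(residue_after: str, rules: Sequence[EnzymeRule]) -> str | None:
    """A flank residue x such that the bond x|residue_after is cleaved."""
    for rule in rules:
        if residue_after in rule.p1prime_exclusions:
            continue
        if rule.p1_residues:
            return sorted(rule.p1_residues)[0]
        for x, y in sorted(rule.p1p1prime_pairs):
            if y == residue_after:
                return x
    return None


def embed_motif(
    host: str,
    motif: str,
    rules: Iterable[EnzymeRule],
) -> str:
    """Return a sequence containing *motif* released intact by ``digest``.

    The motif is appended at the C-terminus behind a flank residue drawn
    from the rules' P1 specificity, so the bond entering the motif is cut
    and no bond follows it.  Raises :class:`MotifError` when the rule set
    cuts inside the motif (the fragment could never survive) or offers no
    flank able to open it.
    """
    rules = list(rules)
    motif = validate_sequence(motif)
    if len(motif) not in (2, 3):
        raise MotifError("motif must be a di- or tripeptide")
    for rule in rules:
        internal = find_cleavage_sites(motif, rule)
        if internal:
            raise MotifError(
                f"rule {rule.name!r} cuts inside motif {motif!r} "
                f"at bond(s) {sorted(internal)}"
            )
    flank = _cut_before(motif[0], rules)
    if flank is None:
        raise MotifError(f"no rule can open a bond before motif {motif!r}")
    host = validate_sequence(host) if host.strip() else ""
    candidate = host + flank + motif
    released = digest(candidate, rules).sequences()
    if motif not in released:  # pragma: no cover - guarded by construction
        raise MotifError(f"construction failed to release {motif!r}")
    return candidate
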