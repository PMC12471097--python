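"""Resistance of released di/tripeptides to microbial proteases.

Each bioactive fragment is re-digested with the two proteases of
gastrointestinal microorganisms — oligopeptidase F and proteinase P1
(lactocepin) — and called *resistant* only if both leave it intact.
Classification is definitionally a :func:`ampdigest.cleavage.digest` call
per enzyme; this module only fixes the scope (di/tripeptides) and report
shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .cleavage import EnzymeRule, digest, load_enzyme_rules
from .records import validate_sequence


@dataclass(frozen=True)
class ResistanceReport:
    """Digestion outcome of one fragment under both microbial proteases."""

    fragment: str
    opf_products: tuple[str, ...]
    p1_products: tuple[str, ...]

    @property
    def resistant_both(self) -> bool:
        return (
            self.opf_products == (self.fragment,)
            and self.p1_products == (self.fragment,)
        )


def _microbial_pair() -> tuple[EnzymeRule, EnzymeRule]:
    rules = load_enzyme_rules()
    return rules["oligopeptidase_f"], rules["proteinase_p1"]


def classify_fragment(
    fragment: str,
    opf_rule: EnzymeRule | None = None,
    p1_rule: EnzymeRule | None = None,
) -> ResistanceReport:
    """Digest *fragment* separately with oligopeptidase F and proteinase P1.

    Only di/tripeptides are in scope (the classifier mirrors the
    resistance screen applied to released bioactive fragments); longer
    substrates should go through :func:`ampdigest.cleavage.digest`
    directly.
    """
    fragment = validate_sequence(fragment)
    if len(fragment) not in (2, 3):
        raise ValueError(
            f"resistance classification is defined for di/tripeptides, "
            f"got length {len(fragment)}"
        )
    if opf_rule is None or p1_rule is None:
        default_opf, default_p1 = _microbial_pair()
        opf_rule = opf_rule or default_opf
        p1_rule = p1_rule or default_p1
    opf = tuple(digest(fragment, [opf_rule]).sequences())
    p1 = tuple(digest(fragment, [p1_rule]).sequences())
    return ResistanceReport(fragment, opf, p1)


def resistance_table(fragments: Iterable[str]) -> list[ResistanceReport]:
    """Classify each fragment, preserving input order."""
    opf_rule, p1_rule = _microbial_pair()
    return [classify_fragment(f, opf_rule, p1_rule) for f in fragments]
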