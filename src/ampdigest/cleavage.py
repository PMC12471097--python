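"""One-pass simultaneous proteolysis driven by bond-specificity rules.

The digestion model is the exhaustive "action of enzymes" convention:
every peptide bond whose P1 (and, for pair rules, P1') context matches any
active enzyme rule is cut at once.  There are no kinetics, no partial
digestion and no missed-cleavage enumeration — the fragment set is a
deterministic function of the sequence and the rule set.

Bonds are indexed 0-based: bond ``i`` joins residues ``i`` and ``i+1``.
Fragments carry 0-based half-open coordinates; reports print 1-based
inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .records import CANONICAL_RESIDUES, PeptideRecord, validate_sequence

GI_ENZYMES = ("pepsin_ph1.3", "trypsin", "chymotrypsin")
MICROBIAL_ENZYMES = ("oligopeptidase_f", "proteinase_p1")


@dataclass(frozen=True)
class EnzymeRule:
    """Bond-cleavage specificity of one protease.

    A bond ``x|y`` is cut when ``x`` is in :attr:`p1_residues` or the
    ordered pair ``(x, y)`` is in :attr:`p1p1prime_pairs`, unless ``y`` is
    in :attr:`p1prime_exclusions`.  Substrates shorter than
    :attr:`min_substrate_length` are left untouched.
    """

    name: str
    ec_number: str = ""
    p1_residues: frozenset[str] = frozenset()
    p1p1prime_pairs: frozenset[tuple[str, str]] = frozenset()
    p1prime_exclusions: frozenset[str] = frozenset()
    min_substrate_length: int = 2

    def __post_init__(self) -> None:
        if not self.p1_residues and not self.p1p1prime_pairs:
            raise ValueError(f"enzyme {self.name!r} has no specificity")
        if self.min_substrate_length < 2:
            raise ValueError("min_substrate_length must be >= 2")
        for res in self.p1_residues | self.p1prime_exclusions:
            if res not in CANONICAL_RESIDUES:
                raise ValueError(f"unknown residue code {res!r} in {self.name!r}")
        for x, y in self.p1p1prime_pairs:
            if x not in CANONICAL_RESIDUES or y not in CANONICAL_RESIDUES:
                raise ValueError(f"unknown residue pair {x + y!r} in {self.name!r}")


@dataclass(frozen=True)
class Fragment:
    sequence: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive


@dataclass(frozen=True)
class FragmentSet:
    """Ordered digestion products of one parent with positional provenance."""

    parent_id: str
    parent_sequence: str
    fragments: tuple[Fragment, ...]
    cut_sites: tuple[int, ...]

    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]

    def __post_init__(self) -> None:
        joined = "".join(f.sequence for f in self.fragments)
        if joined != self.parent_sequence:
            raise ValueError("fragments do not concatenate to the parent")


def find_cleavage_sites(sequence: str, rule: EnzymeRule) -> set[int]:
    """Bond indices cut by *rule* in *sequence* (may be empty)."""
    if len(sequence) < rule.min_substrate_length:
        return set()
    sites = set()
    for i in range(len(sequence) - 1):
        p1, p1prime = sequence[i], sequence[i + 1]
        if p1prime in rule.p1prime_exclusions:
            continue
        if p1 in rule.p1_residues or (p1, p1prime) in rule.p1p1prime_pairs:
            sites.add(i)
    return sites


def digest(
    sequence: str,
    rules: Iterable[EnzymeRule],
    parent_id: str = "",
) -> FragmentSet:
    """Simultaneously digest *sequence* with all *rules*.

    Cut sites are the union over rules; fragments are the maximal runs
    between cuts.  With no matching site the single fragment is the whole
    sequence.
    """
    sequence = validate_sequence(sequence)
    rules = list(rules)
    if not rules:
        raise ValueError("at least one enzyme rule is required")
    cuts = sorted(set().union(*(find_cleavage_sites(sequence, r) for r in rules)))
    bounds = [0] + [c + 1 for c in cuts] + [len(sequence)]
    fragments = tuple(
        Fragment(sequence[a:b], a, b) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return FragmentSet(parent_id, sequence, fragments, tuple(cuts))


def unique_fragments(
    dataset: Iterable[PeptideRecord],
    rules: Iterable[EnzymeRule],
    length_filter: Iterable[int] = (2, 3),
) -> dict[str, list[str]]:
    """Map each released fragment sequence to the sorted ids of its parents.

    Only fragments whose length is in *length_filter* (default: di- and
    tripeptides) are kept; duplicate releases from one parent collapse to
    one entry.
    """
    rules = list(rules)
    lengths = set(length_filter)
    out: dict[str, set[str]] = {}
    for rec in dataset:
        for frag in digest(rec.sequence, rules, rec.apd_id).fragments:
            if len(frag.sequence) in lengths:
                out.setdefault(frag.sequence, set()).add(rec.apd_id)
    return {seq: sorted(ids) for seq, ids in sorted(out.items())}


def _rules_from_mapping(cfg: Mapping) -> dict[str, EnzymeRule]:
    rules = {}
    for name, spec in cfg["enzymes"].items():
        spec = spec or {}
        rules[name] = EnzymeRule(
            name=name,
            ec_number=str(spec.get("ec_number", "")),
            p1_residues=frozenset(spec.get("p1", ())),
            p1p1prime_pairs=frozenset(
                (p[0], p[1]) for p in spec.get("pairs", ())
            ),
            p1prime_exclusions=frozenset(spec.get("p1prime_exclusions", ())),
            min_substrate_length=int(spec.get("min_substrate_length", 2)),
        )
    return rules


def load_enzyme_rules(config_path: str | None = None) -> dict[str, EnzymeRule]:
    """Load enzyme rules from a YAML config.

    With no path, the shipped defaults are returned: the three
    gastrointestinal proteases (pepsin at pH 1.3, trypsin, chymotrypsin)
    plus the two microbial proteases (oligopeptidase F, proteinase P1).
    """
    if config_path is not None:
        with open(config_path, "r", encoding="utf-8") as fh:
            return _rules_from_mapping(yaml.safe_load(fh))
    rules: dict[str, EnzymeRule] = {}
    for asset in ("enzymes_gi.yaml", "enzymes_microbial.yaml"):
        text = resources.files("ampdigest.data").joinpath(asset).read_text()
        rules.update(_rules_from_mapping(yaml.safe_load(text)))
    return rules


def gi_rules() -> list[EnzymeRule]:
    """The default gastrointestinal rule set (pepsin, trypsin, chymotrypsin)."""
    rules = load_enzyme_rules()
    return [rules[name] for name in GI_ENZYMES]


def microbial_rules() -> list[EnzymeRule]:
    """The default microbial rule set (oligopeptidase F, proteinase P1)."""
    rules = load_enzyme_rules()
    return [rules[name] for name in MICROBIAL_ENZYMES]
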