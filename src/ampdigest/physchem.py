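"""Physicochemical descriptors and interpretation flags for short peptides.

Seven descriptors are computed per peptide:

* **Boman index** — mean per-residue side-chain transfer free energy
  (kcal/mol, hydrophilic-positive); > 2.48 is read as high potential for
  binding proteins or membranes.
* **Net charge at pH 7** — Henderson–Hasselbalch sum over the termini and
  ionizable side chains.
* **Theoretical pI** — the pH at which that sum vanishes; the charge
  curve is strictly decreasing in pH, so the root is unique.
* **Instability index** — Guruprasad's dipeptide-weight statistic
  ``(10/L)·Σ DIWV(x_i, x_{i+1})``; > 40 is read as unstable in vitro.
* **Aliphatic index** — Ikai's relative aliphatic side-chain volume
  ``100·(f_A + 2.9·f_V + 3.9·(f_I + f_L))``; > 100 is read here as
  thermostability.
* **GRAVY** — mean Kyte–Doolittle hydropathy (negative = hydrophilic).
* **Water solubility** — ``good`` iff the peptide carries at least one
  charged side chain (D, E, K, R, H), else ``poor``.

Two pKa sets are shipped (see ``data/pka_sets.yaml``): an EMBOSS-style set
for pI and a variant with His 6.0 for the pH-7 charge, mirroring the two
different calculators behind the reference characterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml
from Bio.SeqUtils import ProtParamData
from scipy.optimize import brentq

from .records import CANONICAL_RESIDUES, validate_sequence

#: Boman index above which a peptide is called a strong protein binder.
BOMAN_BINDING_THRESHOLD = 2.48
#: Guruprasad instability index above which a peptide is called unstable.
INSTABILITY_THRESHOLD = 40.0
#: Aliphatic index above which a peptide is called thermostable.
ALIPHATIC_THERMOSTABLE_THRESHOLD = 100.0
#: Maximum length transportable by the intestinal PEPT1/PEPT2 carriers.
PEPT_TRANSPORT_MAX_LENGTH = 3

#: Residues with charged side chains; their presence drives the
#: solubility call.
CHARGED_RESIDUES = frozenset("DEKRH")

_ACID_GROUPS = frozenset({"cterm", "C", "D", "E", "Y"})
_BASE_GROUPS = frozenset({"nterm", "H", "K", "R"})


# ---------------------------------------------------------------------------
# Scales and parameter sets


@lru_cache(maxsize=None)
def kyte_doolittle_scale() -> Mapping[str, float]:
    """Kyte–Doolittle hydropathy values (20 entries, within ±4.5)."""
    scale = dict(ProtParamData.kd)
    assert set(scale) == set(CANONICAL_RESIDUES)
    return scale


@lru_cache(maxsize=None)
def boman_scale() -> Mapping[str, float]:
    """Hydrophilic-positive transfer free energies (kcal/mol) per residue."""
    text = (
        resources.files("ampdigest.data")
        .joinpath("boman_scale.tsv")
        .read_text(encoding="utf-8")
    )
    scale: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("residue"):
            continue
        residue, value = line.split("\t")
        scale[residue] = float(value)
    if set(scale) != set(CANONICAL_RESIDUES):
        raise ValueError("Boman scale asset must cover exactly the 20 residues")
    return scale


class DipeptideInstabilityMatrix:
    """Guruprasad 20×20 dipeptide instability weights (DIWV).

    Unlisted pairs take the neutral default 1.0.  The shipped weights are
    the published matrix as distributed with Biopython's ProtParam data.
    """

    def __init__(
        self,
        weights: Mapping[str, Mapping[str, float]] | None = None,
        default: float = 1.0,
    ) -> None:
        self.default = default
        source = weights if weights is not None else ProtParamData.DIWV
        self._weights = {
            x: {y: float(v) for y, v in row.items()} for x, row in source.items()
        }

    def weight(self, x: str, y: str) -> float:
        return self._weights.get(x, {}).get(y, self.default)


@dataclass(frozen=True)
class PkaSet:
    """pKa values for the termini and ionizable side chains.

    Groups are the two termini (``nterm``/``cterm``) plus side chains of
    C, D, E, Y (acids) and H, K, R (bases).
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not {"nterm", "cterm"} <= set(self.values):
            raise ValueError("pKa set must define both termini")
        for group, pka in self.values.items():
            if group not in _ACID_GROUPS | _BASE_GROUPS:
                raise ValueError(f"unknown ionizable group {group!r}")
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {group!r} outside (0, 14)")


@lru_cache(maxsize=None)
def pka_set(name: str = "pi") -> PkaSet:
    """Load a shipped pKa set: ``"pi"`` or ``"charge"``."""
    text = (
        resources.files("ampdigest.data")
        .joinpath("pka_sets.yaml")
        .read_text(encoding="utf-8")
    )
    sets = yaml.safe_load(text)["pka_sets"]
    if name not in sets:
        raise KeyError(f"unknown pKa set {name!r}; shipped: {sorted(sets)}")
    return PkaSet(name, {g: float(v) for g, v in sets[name].items()})


# ---------------------------------------------------------------------------
# Descriptors


def gravy(sequence: str, scale: Mapping[str, float] | None = None) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value."""
    sequence = validate_sequence(sequence)
    scale = scale if scale is not None else kyte_doolittle_scale()
    return sum(scale[a] for a in sequence) / len(sequence)


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index on mole fractions of A, V, I and L."""
    sequence = validate_sequence(sequence)
    n = len(sequence)
    f = {a: sequence.count(a) / n for a in "AVIL"}
    return 100.0 * (f["A"] + 2.9 * f["V"] + 3.9 * (f["I"] + f["L"]))


def boman_index(sequence: str, scale: Mapping[str, float] | None = None) -> float:
    """Mean per-residue transfer free energy, kcal/mol (hydrophilic-positive)."""
    sequence = validate_sequence(sequence)
    scale = scale if scale is not None else boman_scale()
    return sum(scale[a] for a in sequence) / len(sequence)


def net_charge(sequence: str, ph: float, pkas: PkaSet | None = None) -> float:
    """Henderson–Hasselbalch net charge of *sequence* at *ph*.

    Bases contribute ``+1/(1+10^(pH−pKa))``, acids ``−1/(1+10^(pKa−pH))``,
    over the N-terminus, C-terminus and every ionizable side chain with a
    pKa in the set.
    """
    sequence = validate_sequence(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    pkas = pkas if pkas is not None else pka_set("charge")
    groups = ["nterm", "cterm"] + [a for a in sequence if a in pkas.values]
    charge = 0.0
    for group in groups:
        pka = pkas.values[group]
        if group in _BASE_GROUPS:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, pkas: PkaSet | None = None) -> float:
    """The unique pH in [0, 14] where the net charge vanishes.

    The charge curve is strictly decreasing in pH (every term is), so a
    bracketing root search converges to the single root; the bracket is
    guaranteed because the N-terminal base dominates at pH 0 and the
    C-terminal acid at pH 14.
    """
    sequence = validate_sequence(sequence)
    pkas = pkas if pkas is not None else pka_set("pi")
    return float(brentq(lambda ph: net_charge(sequence, ph, pkas), 0.0, 14.0,
                        xtol=1e-9))


def instability_index(
    sequence: str, matrix: DipeptideInstabilityMatrix | None = None
) -> float:
    """Guruprasad instability index ``(10/L)·Σ DIWV(x_i, x_{i+1})``.

    Undefined for single residues (no dipeptide term): length 1 raises.
    """
    sequence = validate_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("instability index requires length >= 2")
    matrix = matrix if matrix is not None else DipeptideInstabilityMatrix()
    total = sum(
        matrix.weight(x, y) for x, y in zip(sequence[:-1], sequence[1:])
    )
    return 10.0 / len(sequence) * total


def solubility_class(sequence: str) -> str:
    """``"good"`` iff the peptide has a charged side chain (D/E/K/R/H)."""
    sequence = validate_sequence(sequence)
    return "good" if set(sequence) & CHARGED_RESIDUES else "poor"


# ---------------------------------------------------------------------------
# Profile assembly


@dataclass(frozen=True)
class PhysChemProfile:
    """All seven descriptors plus interpretation flags for one peptide.

    Descriptor fields hold unrounded values; flags are derived from the
    unrounded values (thresholds are module constants).  Use
    :meth:`as_report_row` for display rounding.
    """

    sequence: str
    boman: float
    net_charge_ph7: float
    pi: float
    instability: float
    aliphatic: float
    gravy: float
    solubility: str
    high_binding: bool
    unstable: bool
    thermostable: bool
    pept_transportable: bool

    def as_report_row(self) -> dict[str, object]:
        """Display-rounded row mirroring the standard report layout.

        Most descriptors round to 2 decimals and the charge to 1; the
        Boman index is truncated toward zero at 2 decimals, matching the
        display convention of the reference calculator.
        """
        return {
            "sequence": self.sequence,
            "boman": math.trunc(self.boman * 100) / 100 + 0.0,
            "net_charge": round(self.net_charge_ph7, 1) + 0.0,
            "pI": round(self.pi, 2) + 0.0,
            "instability": round(self.instability, 2) + 0.0,
            "aliphatic": round(self.aliphatic, 2) + 0.0,
            "gravy": round(self.gravy, 2) + 0.0,
            "solubility": self.solubility,
        }


def classify_profile(
    boman: float, instability: float, aliphatic: float, length: int
) -> dict[str, bool]:
    """Interpretation flags from unrounded descriptor values."""
    return {
        "high_binding": boman > BOMAN_BINDING_THRESHOLD,
        "unstable": instability > INSTABILITY_THRESHOLD,
        "thermostable": aliphatic > ALIPHATIC_THERMOSTABLE_THRESHOLD,
        "pept_transportable": length <= PEPT_TRANSPORT_MAX_LENGTH,
    }


def physchem_profile(sequence: str) -> PhysChemProfile:
    """Compute the full descriptor profile with the shipped scales/pKa sets."""
    sequence = validate_sequence(sequence)
    b = boman_index(sequence)
    inst = instability_index(sequence)
    ali = aliphatic_index(sequence)
    flags = classify_profile(b, inst, ali, len(sequence))
    return PhysChemProfile(
        sequence=sequence,
        boman=b,
        net_charge_ph7=net_charge(sequence, 7.0, pka_set("charge")),
        pi=isoelectric_point(sequence, pka_set("pi")),
        instability=inst,
        aliphatic=ali,
        gravy=gravy(sequence),
        solubility=solubility_class(sequence),
        **flags,
    )
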