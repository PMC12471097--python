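"""End-to-end orchestration: digest → annotate → resistance → physchem.

``run_pipeline`` turns a peptide source (FASTA file, the built-in
57-peptide panel, or a synthetic generator config) into the three report
tables: the activity-major release table, the microbial-resistance table
and the physicochemical characterization table.  Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import activity_profile
from .cleavage import GI_ENZYMES, gi_rules, load_enzyme_rules
from .physchem import physchem_profile
from .records import PeptideRecord, load_reference_dataset, parse_fasta
from .resistance import resistance_table
from .synth import GeneratorConfig, random_peptides

_ASSETS = (
    "reference_peptides.tsv",
    "activity_table.tsv",
    "enzymes_gi.yaml",
    "enzymes_microbial.yaml",
    "boman_scale.tsv",
    "pka_sets.yaml",
)

TABLE3_COLUMNS = [
    "sequence", "boman", "net_charge", "pI",
    "instability", "aliphatic", "gravy", "solubility",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``fasta_path`` / ``use_fixture`` / ``synthetic``."""

    fasta_path: str | None = None
    use_fixture: bool = False
    synthetic: GeneratorConfig | None = None
    enzyme_config: str | None = None
    out_dir: str = "results"
    formats: tuple[str, ...] = ("tsv",)

    def __post_init__(self) -> None:
        chosen = sum(
            (self.fasta_path is not None, self.use_fixture, self.synthetic is not None)
        )
        if chosen != 1:
            raise ValueError("exactly one input source must be configured")
        unknown = set(self.formats) - {"tsv", "json"}
        if unknown:
            raise ValueError(f"unknown report formats: {sorted(unknown)}")


def _load_input(config: PipelineConfig) -> list[PeptideRecord]:
    if config.use_fixture:
        return load_reference_dataset()
    if config.synthetic is not None:
        return random_peptides(config.synthetic)
    return parse_fasta(config.fasta_path)


def _asset_checksums() -> dict[str, str]:
    out = {}
    for name in _ASSETS:
        data = resources.files("ampdigest.data").joinpath(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the full analysis; returns the three reports plus run metadata."""
    dataset = _load_input(config)
    if config.enzyme_config is not None:
        rules_map = load_enzyme_rules(config.enzyme_config)
        digestion_rules = [rules_map[name] for name in GI_ENZYMES]
    else:
        digestion_rules = gi_rules()

    annotated = activity_profile(dataset, digestion_rules)
    table1 = pd.DataFrame(
        [
            {"activity": a, "fragment": f, "source_ids": ";".join(ids)}
            for a, f, ids in annotated
        ],
        columns=["activity", "fragment", "source_ids"],
    )

    # Bioactive fragments in first-appearance order of the activity report.
    fragments: list[str] = []
    for _, frag, _ in annotated:
        if frag not in fragments:
            fragments.append(frag)

    reports = resistance_table(fragments)
    table2 = pd.DataFrame(
        [
            {
                "fragment": r.fragment,
                "opf_products": ";".join(r.opf_products),
                "p1_products": ";".join(r.p1_products),
                "resistant_both": r.resistant_both,
            }
            for r in reports
        ],
        columns=["fragment", "opf_products", "p1_products", "resistant_both"],
    )

    profiles = [physchem_profile(f) for f in fragments]
    table3 = pd.DataFrame(
        [p.as_report_row() for p in profiles], columns=TABLE3_COLUMNS
    )
    flags = pd.DataFrame(
        [
            {
                "sequence": p.sequence,
                "high_binding": p.high_binding,
                "unstable": p.unstable,
                "thermostable": p.thermostable,
                "pept_transportable": p.pept_transportable,
            }
            for p in profiles
        ]
    )

    metadata = {
        "version": __version__,
        "n_input_peptides": len(dataset),
        "n_bioactive_fragments": len(fragments),
        "digestion_rules": [r.name for r in digestion_rules],
        "asset_checksums": _asset_checksums(),
        "synthetic_seed": (
            config.synthetic.seed if config.synthetic is not None else None
        ),
    }
    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "flags": flags,
        "metadata": metadata,
    }


def write_reports(results: dict[str, object], config: PipelineConfig) -> list[Path]:
    """Write the reports to ``config.out_dir``; returns the paths written."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {k: results[k] for k in ("table1", "table2", "table3", "flags")}
    if "tsv" in config.formats:
        for name, frame in tables.items():
            path = out_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
    if "json" in config.formats:
        payload = {
            name: frame.to_dict(orient="records") for name, frame in tables.items()
        }
        payload["metadata"] = results["metadata"]
        path = out_dir / "reports.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(
        json.dumps(results["metadata"], indent=2, sort_keys=True) + "\n"
    )
    written.append(meta_path)
    return written
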