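"""Bioactivity annotation of released di/tripeptides.

The annotation source is a static snapshot of known bioactive short
peptides (ACE inhibitors, DPP-IV inhibitors, antioxidative peptides, …)
shipped as a TSV asset.  It is a lookup, not a predictor: fragments absent
from the table are reported in a separate "unannotated" bucket rather
than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .records import PeptideRecord, validate_sequence
from .cleavage import EnzymeRule, unique_fragments

#: Controlled activity vocabulary.
ACTIVITIES = (
    "ACE inhibitor",
    "Antioxidative",
    "Dipeptidyl peptidase IV inhibitor",
    "Stimulating",
    "Renin inhibitor",
    "Dipeptidyl peptidase III inhibitor",
    "Neuropeptide",
    "ACE2 inhibitor",
    "Xaa-Pro inhibitor",
    "Lactocepin inhibitor",
    "Acylaminoacyl peptidase inhibitor",
    "Tripeptidyl peptidase II inhibitor",
    "Neprilysin inhibitor",
)

# Spelling variants seen in upstream sources, normalized on load.
_ACTIVITY_ALIASES = {
    "Xaa-pro inhibitor": "Xaa-Pro inhibitor",
}


@dataclass(frozen=True)
class ActivityRecord:
    """One (activity, fragment) row of the annotation snapshot."""

    activity: str
    fragment: str
    source_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity label {self.activity!r}")
        if len(self.fragment) not in (2, 3):
            raise ValueError(
                f"annotation fragment {self.fragment!r} is not a di/tripeptide"
            )


def load_activity_table() -> list[ActivityRecord]:
    """Load the shipped activity snapshot, one record per (activity, fragment)."""
    text = (
        resources.files("ampdigest.data")
        .joinpath("activity_table.tsv")
        .read_text(encoding="utf-8")
    )
    records = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        activity, fragment, ids = line.split("\t")
        activity = _ACTIVITY_ALIASES.get(activity, activity)
        records.append(
            ActivityRecord(
                activity,
                validate_sequence(fragment),
                tuple(ids.split(";")),
            )
        )
    return records


def activities_of(fragment: str) -> set[str]:
    """All activity labels recorded for *fragment* (empty set if unknown)."""
    return {
        rec.activity
        for rec in load_activity_table()
        if rec.fragment == fragment
    }


def annotate_fragments(
    fragment_map: Mapping[str, Iterable[str]],
) -> tuple[list[tuple[str, str, list[str]]], dict[str, list[str]]]:
    """Join a fragment → parents map with the activity table.

    Returns ``(annotated, unannotated)`` where *annotated* is a list of
    ``(activity, fragment, sorted parent ids)`` triples ordered by
    activity (vocabulary order), fragment, then parents, and
    *unannotated* holds the fragments with no recorded activity.  The
    join is lossless: every input fragment lands in exactly one bucket.
    """
    table: dict[str, list[str]] = {}
    for rec in load_activity_table():
        table.setdefault(rec.fragment, []).append(rec.activity)

    annotated: list[tuple[str, str, list[str]]] = []
    unannotated: dict[str, list[str]] = {}
    for fragment, parents in fragment_map.items():
        fragment = validate_sequence(fragment)
        parents = sorted(parents)
        if fragment in table:
            for activity in table[fragment]:
                annotated.append((activity, fragment, parents))
        else:
            unannotated[fragment] = parents
    rank = {a: i for i, a in enumerate(ACTIVITIES)}
    annotated.sort(key=lambda t: (rank[t[0]], t[1], t[2]))
    return annotated, unannotated


def activity_profile(
    dataset: Iterable[PeptideRecord],
    rules: Iterable[EnzymeRule],
) -> list[tuple[str, str, list[str]]]:
    """Digest *dataset*, keep di/tripeptides, and annotate them.

    The result is the activity-major report: one row per
    ``(activity, fragment)`` with the sorted parent accessions that
    release the fragment under *rules*.
    """
    fragment_map = unique_fragments(dataset, rules, (2, 3))
    annotated, _ = annotate_fragments(fragment_map)
    return annotated
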