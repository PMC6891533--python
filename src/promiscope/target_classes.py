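"""Target-class assignment and multiclass-ligand identification.

Targets are assigned to one of eight classes — Enzymes, G protein-coupled
receptors, Transcription factors, Ion channels, Receptors, Transporters,
Others, Unclassified — by ordered keyword rules over protein and family
names (specific patterns take precedence over the generic "receptor"
fallback).  "Others" is an aggregate of minor families and is only assigned
through an explicit ``class_label`` in the target table.

A multiclass ligand is a highly promiscuous compound (PD >= 10 by default)
active against targets from at least two classes.  Its complement among the
highly promiscuous compounds — those whose activity stays within one class —
and the broader set of single-class promiscuous compounds (PD >= 2, one
class) are derived here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from promiscope.ingest import ActivityProfile, TargetRecord

_DATA_DIR = Path(__file__).parent / "data"

CLASS_LABELS: tuple[str, ...] = (
    "Enzymes",
    "G protein-coupled receptors",
    "Transcription factors",
    "Ion channels",
    "Receptors",
    "Transporters",
    "Others",
    "Unclassified",
)

UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class ClassRule:
    pattern: str  # lower-case substring matched against names
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


class ClassScheme:
    """Ordered keyword → class rules; first matching rule wins."""

    def __init__(self, rules: Sequence[ClassRule]):
        self.rules = list(rules)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            [ClassRule(r["pattern"].lower(), r["class"]) for r in data["rules"]]
        )

    @classmethod
    def default(cls) -> "ClassScheme":
        return cls.from_yaml(_DATA_DIR / "class_scheme.yaml")


def assign_class(target: TargetRecord, scheme: ClassScheme) -> str:
    """Deterministically assign a single class label to a target.

    An explicit ``class_label`` on the record wins outright (this is the
    only way a target becomes "Others"); otherwise the first keyword rule
    matching the family or protein name applies; otherwise Unclassified.
    """
    if target.class_label:
        if target.class_label not in CLASS_LABELS:
            raise ValueError(
                f"{target.target_id}: unknown explicit class label "
                f"{target.class_label!r}"
            )
        return target.class_label
    haystack = f"{target.family_name} {target.protein_name}".lower()
    for rule in scheme.rules:
        if rule.pattern in haystack:
            return rule.label
    return UNCLASSIFIED


def class_table(
    targets: Mapping[str, TargetRecord], scheme: ClassScheme
) -> dict[str, int]:
    """Number of targets per class (the class-size table); a partition, so
    the counts sum to the number of targets."""
    counts = {label: 0 for label in CLASS_LABELS}
    for t in targets.values():
        counts[assign_class(t, scheme)] += 1
    return counts


@dataclass(frozen=True)
class ClassProfile:
    """Per-compound view of screening activity at class resolution."""

    compound_id: str
    pd: int
    active_classes: frozenset[str]
    tested_classes: frozenset[str]
    is_multiclass: bool

    def __post_init__(self) -> None:
        if not self.active_classes <= self.tested_classes:
            raise ValueError(
                f"{self.compound_id}: active classes not a subset of tested classes"
            )


def class_profile(
    profile: ActivityProfile,
    targets: Mapping[str, TargetRecord],
    scheme: ClassScheme,
    pd_hi: int = 10,
) -> ClassProfile:
    """Resolve a compound's activity profile to target classes.

    is_multiclass iff PD >= pd_hi and the active targets span >= 2 classes.
    Every target id in the profile must be resolvable.
    """
    missing = sorted(
        (profile.tested_targets | profile.discarded_targets) - set(targets)
    )
    if missing:
        raise KeyError(
            f"{profile.compound_id}: unknown target id(s) {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    label_of = {
        tid: assign_class(targets[tid], scheme) for tid in profile.tested_targets
    }
    active = frozenset(label_of[tid] for tid in profile.active_targets)
    tested = frozenset(label_of.values())
    return ClassProfile(
        compound_id=profile.compound_id,
        pd=profile.pd,
        active_classes=active,
        tested_classes=tested,
        is_multiclass=(profile.pd >= pd_hi and len(active) >= 2),
    )


def class_count_histogram(
    class_profiles: Iterable[ClassProfile], pd_hi: int = 10
) -> dict[int, int]:
    """Distribution of highly promiscuous compounds (PD >= pd_hi) over the
    number of classes their active targets span.  Totals are conserved: the
    histogram sums to the number of PD >= pd_hi compounds."""
    hist: dict[int, int] = {}
    for cp in class_profiles:
        if cp.pd >= pd_hi:
            k = len(cp.active_classes)
            hist[k] = hist.get(k, 0) + 1
    return hist


def single_class_promiscuous(
    class_profiles: Iterable[ClassProfile],
) -> set[str]:
    """Compounds exclusively active against multiple targets of one class:
    PD >= 2 with exactly one active class."""
    return {
        cp.compound_id
        for cp in class_profiles
        if cp.pd >= 2 and len(cp.active_classes) == 1
    }
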