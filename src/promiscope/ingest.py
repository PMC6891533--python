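"""Parsing and aggregation of compound, target and activity-call tables.

Screening data arrive as three tab-separated tables: compounds (id + SMILES),
activity calls (compound, assay, target, active/inactive) and targets
(id, protein name, family name, optional explicit class label).  This module
standardizes structures, collapses repeated assay calls into per-compound
activity profiles — discarding compound–target pairs with contradictory
calls — and selects extensively tested compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; rejections are reported
# through StandardizationError / rejection logs instead.
RDLogger.DisableLog("rdApp.*")

OUTCOME_ACTIVE = "active"
OUTCOME_INACTIVE = "inactive"
VALID_OUTCOMES = frozenset({OUTCOME_ACTIVE, OUTCOME_INACTIVE})


class StandardizationError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized.

    Carries the offending input so callers can log and skip the record
    rather than silently dropping it.
    """

    def __init__(self, raw_smiles: str, reason: str = "unparseable SMILES"):
        self.raw_smiles = raw_smiles
        self.reason = reason
        super().__init__(f"{reason}: {raw_smiles!r}")


@dataclass(frozen=True)
class Molecule:
    """A standardized structure keyed by an opaque compound identifier."""

    compound_id: str
    smiles: str  # canonical form after standardization
    n_heavy_atoms: int

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles is canonical by construction
            raise StandardizationError(self.smiles, "stored SMILES failed to re-parse")
        return mol


@dataclass(frozen=True)
class ActivityRecord:
    """One qualitative assay call: a compound tested on a target.

    Only the binary outcome is kept; potency values are deliberately out of
    scope because qualitative screens rarely report comparable ones.
    """

    compound_id: str
    assay_id: str
    target_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in VALID_OUTCOMES:
            raise ValueError(
                f"unknown outcome token {self.outcome!r} "
                f"(expected one of {sorted(VALID_OUTCOMES)})"
            )


@dataclass(frozen=True)
class ActivityProfile:
    """Aggregated per-compound view of the screening matrix.

    ``tested_targets`` holds targets with a consistent call (active or
    inactive); targets with contradictory duplicate calls are moved to
    ``discarded_targets`` and count neither as tested nor as active.
    The promiscuity degree PD is ``len(active_targets)``.
    """

    compound_id: str
    tested_targets: frozenset[str]
    active_targets: frozenset[str]
    discarded_targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.active_targets <= self.tested_targets:
            raise ValueError(
                f"{self.compound_id}: active targets not a subset of tested targets"
            )
        if self.discarded_targets & self.tested_targets:
            raise ValueError(
                f"{self.compound_id}: discarded targets overlap tested targets"
            )

    @property
    def pd(self) -> int:
        return len(self.active_targets)

    @property
    def n_tested(self) -> int:
        return len(self.tested_targets)


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    protein_name: str = ""
    family_name: str = ""
    class_label: str = ""  # optional explicit class; empty = classify by keywords


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_molecule(raw_smiles: str, compound_id: str = "") -> Molecule:
    """Standardize a raw SMILES into a canonical :class:`Molecule`.

    The recipe keeps the largest organic fragment (stripping salts and
    solvents), neutralizes simple charges, and canonicalizes the tautomer as
    given (no tautomer enumeration).  The recipe is idempotent: running it on
    its own output returns the identical canonical SMILES.

    Raises
    ------
    StandardizationError
        If the input is empty or does not parse.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise StandardizationError(raw_smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError(raw_smiles)
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 1:
        raise StandardizationError(raw_smiles, "no heavy atoms after standardization")
    return Molecule(
        compound_id=compound_id,
        smiles=Chem.MolToSmiles(mol),
        n_heavy_atoms=n_heavy,
    )


def read_compounds(
    path: str | Path,
) -> tuple[dict[str, Molecule], list[tuple[str, str, str]]]:
    """Read a compounds.tsv (columns compound_id, smiles) and standardize.

    Returns (molecules keyed by compound id, rejected rows as
    (compound_id, raw_smiles, reason) tuples).  Rejections are logged,
    never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["compound_id", "smiles"], path)
    molecules: dict[str, Molecule] = {}
    rejected: list[tuple[str, str, str]] = []
    for row in df.itertuples(index=False):
        try:
            molecules[row.compound_id] = standardize_molecule(
                row.smiles, row.compound_id
            )
        except StandardizationError as err:
            log.warning("rejecting compound %s: %s", row.compound_id, err)
            rejected.append((row.compound_id, row.smiles, err.reason))
    return molecules, rejected


def write_rejects(rejected: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(rejected, columns=["compound_id", "smiles", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def read_activities(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["compound_id", "assay_id", "target_id", "outcome"], path)
    return [
        ActivityRecord(r.compound_id, r.assay_id, r.target_id, r.outcome)
        for r in df.itertuples(index=False)
    ]


def read_targets(path: str | Path) -> dict[str, TargetRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["target_id", "protein_name"], path)
    if "family_name" not in df.columns:
        df["family_name"] = ""
    if "class_label" not in df.columns:
        df["class_label"] = ""
    targets: dict[str, TargetRecord] = {}
    for r in df.itertuples(index=False):
        if r.target_id in targets:
            raise ValueError(f"duplicate target_id {r.target_id!r} in {path}")
        targets[r.target_id] = TargetRecord(
            r.target_id, r.protein_name, r.family_name, r.class_label
        )
    return targets


def aggregate_profiles(
    records: Iterable[ActivityRecord],
) -> dict[str, ActivityProfile]:
    """Collapse assay calls into one consistent profile per compound.

    Each compound–target pair ends up in exactly one of three places:
    ``active_targets`` (all calls active), tested-but-inactive (all calls
    inactive), or ``discarded_targets`` (at least one call of each kind).
    Aggregation is order-independent and consistent duplicates collapse.
    """
    # pair -> set of outcomes observed
    outcomes: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        if rec.outcome not in VALID_OUTCOMES:
            raise ValueError(f"unknown outcome token {rec.outcome!r}")
        outcomes.setdefault(rec.compound_id, {}).setdefault(
            rec.target_id, set()
        ).add(rec.outcome)

    profiles: dict[str, ActivityProfile] = {}
    for cid, per_target in outcomes.items():
        tested: set[str] = set()
        active: set[str] = set()
        discarded: set[str] = set()
        for tid, seen in per_target.items():
            if len(seen) > 1:
                discarded.add(tid)
            elif OUTCOME_ACTIVE in seen:
                tested.add(tid)
                active.add(tid)
            else:
                tested.add(tid)
        profiles[cid] = ActivityProfile(
            compound_id=cid,
            tested_targets=frozenset(tested),
            active_targets=frozenset(active),
            discarded_targets=frozenset(discarded),
        )
    return profiles


def select_extensively_tested(
    profiles: Mapping[str, ActivityProfile], min_targets: int = 100
) -> dict[str, ActivityProfile]:
    """Keep only compounds tested against at least ``min_targets`` distinct
    targets (after conflict discarding).  The default of 100 matches the
    convention for extensively assayed screening compounds."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    return {
        cid: p for cid, p in profiles.items() if p.n_tested >= min_targets
    }


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
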