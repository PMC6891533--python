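"""Matched molecular pairs and promiscuity cliffs.

An MMP is a pair of compounds that differ only by a chemical modification at
a single site: both reconstruct from an identical core plus their own
substituent.  Pairs are found by single-cut fragmentation — every acyclic
single bond between heavy atoms is broken once, and additionally every
hydrogen position is treated as a cut with a hydrogen "substituent" so that
H -> Cl or H -> CH3 exchanges qualify — followed by exact-match indexing on
the canonical core string.

Transformation size restrictions keep pairs chemically meaningful analog
pairs rather than arbitrary decompositions: substituents are limited to 13
heavy atoms, the core must be at least twice the substituent size, and the
two exchanged substituents may differ by at most 8 heavy atoms.

A promiscuity cliff (PC) is an MMP joining a highly promiscuous compound
(PD >= 10) to a non-promiscuous (PD = 1) or consistently inactive (PD = 0)
analog; the number of tested targets the two analogs share is carried along
as a confidence measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdmolops

from promiscope.ingest import ActivityProfile, Molecule

log = logging.getLogger(__name__)

#: canonical token used for a hydrogen substituent (zero heavy atoms)
H_SUBSTITUENT = "[*][H]"


@dataclass(frozen=True)
class SizeRestrictions:
    """Transformation size restrictions for MMP generation."""

    max_substituent_heavy_atoms: int = 13
    min_core_to_substituent_ratio: float = 2.0
    max_transformation_difference_heavy_atoms: int = 8

    def __post_init__(self) -> None:
        if (
            self.max_substituent_heavy_atoms <= 0
            or self.min_core_to_substituent_ratio <= 0
            or self.max_transformation_difference_heavy_atoms <= 0
        ):
            raise ValueError("size restrictions must be positive")

    def fragment_ok(self, core_size: int, substituent_size: int) -> bool:
        return (
            substituent_size <= self.max_substituent_heavy_atoms
            and core_size >= self.min_core_to_substituent_ratio * substituent_size
        )

    def pair_ok(self, sub_size_a: int, sub_size_b: int) -> bool:
        return (
            abs(sub_size_a - sub_size_b)
            <= self.max_transformation_difference_heavy_atoms
        )


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition of a compound into core + substituent.

    Both fragments carry one attachment point (a wildcard atom) and are in
    canonical form so cores can be compared by string equality.
    """

    compound_id: str
    core: str
    substituent: str
    core_size: int
    substituent_size: int


def _heavy_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _bond_cuts(mol: Chem.Mol, compound_id: str) -> list[tuple[str, str, int, int]]:
    """All (frag_a, frag_b, size_a, size_b) from cutting one eligible bond:
    an acyclic single bond between two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        frag = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:  # pragma: no cover - acyclic bond always splits in two
            continue
        smis = [Chem.MolToSmiles(p) for p in pieces]
        sizes = [
            sum(1 for at in p.GetAtoms() if at.GetAtomicNum() > 1) for p in pieces
        ]
        out.append((smis[0], smis[1], sizes[0], sizes[1]))
    return out


def _hydrogen_cuts(mol: Chem.Mol) -> set[str]:
    """Canonical cores obtained by replacing one hydrogen with an
    attachment point (substituent = hydrogen, zero heavy atoms)."""
    cores: set[str] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() == 0:
            continue
        rw = Chem.RWMol(mol)
        a = rw.GetAtomWithIdx(atom.GetIdx())
        if a.GetNumExplicitHs() > 0:
            a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(atom.GetIdx(), dummy, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(rw)
        except Exception:  # e.g. aromaticity cannot accommodate the cut
            continue
        cores.add(Chem.MolToSmiles(rw))
    return cores


def enumerate_single_cuts(
    mol: Molecule | Chem.Mol,
    restrictions: SizeRestrictions | None = None,
    include_hydrogen: bool = False,
    compound_id: str | None = None,
) -> list[Fragmentation]:
    """Enumerate single-cut fragmentations of one molecule.

    Without restrictions the larger fragment is taken as the core (both
    orientations are emitted on a size tie); with restrictions every
    orientation satisfying the per-fragment rules is emitted.  With
    ``include_hydrogen`` each hydrogen position additionally yields a
    (full-molecule core, hydrogen substituent) fragmentation, which is what
    makes H -> X exchanges discoverable.

    Molecules with no eligible bond (e.g. all bonds in rings, or a single
    heavy atom) yield an empty list.
    """
    if isinstance(mol, Molecule):
        compound_id = compound_id or mol.compound_id
        rdmol = mol.to_rdkit()
    else:
        rdmol = mol
        compound_id = compound_id or ""

    frags: set[Fragmentation] = set()
    for fa, fb, sa, sb in _bond_cuts(rdmol, compound_id):
        orientations: list[tuple[str, str, int, int]] = []
        if restrictions is None:
            if sa >= sb:
                orientations.append((fa, fb, sa, sb))
            if sb >= sa:
                orientations.append((fb, fa, sb, sa))
        else:
            if restrictions.fragment_ok(core_size=sa, substituent_size=sb):
                orientations.append((fa, fb, sa, sb))
            if restrictions.fragment_ok(core_size=sb, substituent_size=sa):
                orientations.append((fb, fa, sb, sa))
        for core, sub, cs, ss in orientations:
            frags.add(Fragmentation(compound_id, core, sub, cs, ss))

    if include_hydrogen:
        n_heavy = _heavy_count(rdmol)
        for core in _hydrogen_cuts(rdmol):
            if restrictions is None or restrictions.fragment_ok(n_heavy, 0):
                frags.add(Fragmentation(compound_id, core, H_SUBSTITUENT, n_heavy, 0))

    return sorted(frags, key=lambda f: (f.core, f.substituent))


@dataclass(frozen=True)
class MatchedMolecularPair:
    """Two compounds sharing an identical core, differing in one
    substituent.  ``compound_a`` < ``compound_b`` by identifier; the
    transformation reads "substituent_a >> substituent_b"."""

    compound_a: str
    compound_b: str
    core: str
    substituent_a: str
    substituent_b: str
    core_size: int
    substituent_size_a: int
    substituent_size_b: int

    def __post_init__(self) -> None:
        if self.compound_a == self.compound_b:
            raise ValueError("an MMP requires two distinct compounds")
        if self.substituent_a == self.substituent_b:
            raise ValueError("an MMP requires two distinct substituents")

    @property
    def transformation(self) -> str:
        return f"{self.substituent_a}>>{self.substituent_b}"

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.compound_a, self.compound_b)


def find_mmps(
    molecules: Mapping[str, Molecule] | Iterable[Molecule],
    restrictions: SizeRestrictions | None = None,
) -> list[MatchedMolecularPair]:
    """Find all matched molecular pairs by core indexing.

    Every compound is fragmented (bond cuts and hydrogen cuts) under the
    size restrictions; fragmentations are grouped by canonical core, and two
    compounds sharing a core with different substituents within the
    transformation-difference limit form an MMP.  When a pair matches on
    several cores, the decomposition with the largest core (the smallest
    transformation) is kept, so each unordered pair appears at most once.
    The result is independent of input order.
    """
    if restrictions is None:
        restrictions = SizeRestrictions()
    mols = (
        list(molecules.values())
        if isinstance(molecules, Mapping)
        else list(molecules)
    )
    ids = [m.compound_id for m in mols]
    if len(ids) != len(set(ids)):
        raise ValueError("compound ids must be unique")

    index: dict[str, list[Fragmentation]] = {}
    for mol in mols:
        for frag in enumerate_single_cuts(
            mol, restrictions=restrictions, include_hydrogen=True
        ):
            index.setdefault(frag.core, []).append(frag)

    best: dict[tuple[str, str], MatchedMolecularPair] = {}
    for core in sorted(index):
        group = index[core]
        if len(group) < 2:
            continue
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                fi, fj = group[i], group[j]
                if fi.compound_id == fj.compound_id:
                    continue
                if fi.substituent == fj.substituent:
                    continue
                if not restrictions.pair_ok(
                    fi.substituent_size, fj.substituent_size
                ):
                    continue
                if fi.compound_id > fj.compound_id:
                    fi, fj = fj, fi
                mmp = MatchedMolecularPair(
                    compound_a=fi.compound_id,
                    compound_b=fj.compound_id,
                    core=core,
                    substituent_a=fi.substituent,
                    substituent_b=fj.substituent,
                    core_size=fi.core_size,
                    substituent_size_a=fi.substituent_size,
                    substituent_size_b=fj.substituent_size,
                )
                prev = best.get(mmp.pair_key)
                if (
                    prev is None
                    or mmp.core_size > prev.core_size
                    or (
                        mmp.core_size == prev.core_size
                        and (mmp.core, mmp.transformation)
                        < (prev.core, prev.transformation)
                    )
                ):
                    best[mmp.pair_key] = mmp
    return [best[k] for k in sorted(best)]


def reassemble(core: str, substituent: str) -> str:
    """Reattach a substituent to a core and return the canonical SMILES of
    the whole molecule (used to verify MMP decompositions round-trip)."""
    core_mol = Chem.MolFromSmiles(core)
    if core_mol is None:
        raise ValueError(f"core does not parse: {core!r}")
    if substituent == H_SUBSTITUENT:
        rw = Chem.RWMol(core_mol)
        for atom in list(rw.GetAtoms()):
            if atom.GetAtomicNum() == 0:
                rw.RemoveAtom(atom.GetIdx())
                break
        Chem.SanitizeMol(rw)
        return Chem.MolToSmiles(rw)
    sub_mol = Chem.MolFromSmiles(substituent)
    if sub_mol is None:
        raise ValueError(f"substituent does not parse: {substituent!r}")
    for m in (core_mol, sub_mol):
        for atom in m.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(1)
    combined = Chem.CombineMols(core_mol, sub_mol)
    joined = rdmolops.molzip(combined)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


@dataclass(frozen=True)
class PromiscuityCliff:
    """An MMP whose members sit on opposite ends of the promiscuity scale."""

    promiscuous_id: str
    partner_id: str
    mmp: MatchedMolecularPair
    pd_promiscuous: int
    pd_partner: int
    shared_tested: int

    def __post_init__(self) -> None:
        if self.pd_promiscuous <= self.pd_partner:
            raise ValueError("cliff requires pd_promiscuous > pd_partner")
        if self.shared_tested < 0:
            raise ValueError("shared_tested must be non-negative")


def detect_promiscuity_cliffs(
    mmps: Sequence[MatchedMolecularPair],
    profiles: Mapping[str, ActivityProfile],
    pd_hi: int = 10,
    pd_lo: int = 1,
) -> list[PromiscuityCliff]:
    """Select the MMPs that are promiscuity cliffs.

    A cliff joins a member with PD >= ``pd_hi`` to one with PD <= ``pd_lo``.
    ``shared_tested`` is the size of the tested-target intersection.  MMPs
    with a member lacking a profile are skipped with a log message.
    """
    cliffs: list[PromiscuityCliff] = []
    for mmp in mmps:
        pa = profiles.get(mmp.compound_a)
        pb = profiles.get(mmp.compound_b)
        if pa is None or pb is None:
            missing = [
                cid
                for cid, p in ((mmp.compound_a, pa), (mmp.compound_b, pb))
                if p is None
            ]
            log.warning("MMP %s skipped: no profile for %s", mmp.pair_key, missing)
            continue
        for hi, lo in ((pa, pb), (pb, pa)):
            if hi.pd >= pd_hi and lo.pd <= pd_lo:
                cliffs.append(
                    PromiscuityCliff(
                        promiscuous_id=hi.compound_id,
                        partner_id=lo.compound_id,
                        mmp=mmp,
                        pd_promiscuous=hi.pd,
                        pd_partner=lo.pd,
                        shared_tested=len(
                            hi.tested_targets & lo.tested_targets
                        ),
                    )
                )
                break
    return cliffs
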