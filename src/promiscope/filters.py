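"""Assay-liability filtering: PAINS, aggregator likeness, medchem rules.

Promiscuity analysis is uniquely vulnerable to false-positive assay signals:
a single frequent hitter looks like a genuine multitarget ligand.  Three
filter families are applied and a compound must pass all of them:

* three named PAINS substructure catalogs (a compound is PAINS-flagged if
  any catalog matches);
* an aggregator-likeness heuristic: Tanimoto similarity >= 0.85 on a Morgan
  circular fingerprint to a known colloidal aggregator AND calculated
  logP >= 3;
* a data-driven medicinal-chemistry rule engine (SMARTS rules grouped in
  categories such as acylating agents, aldehydes, chelators, reactive
  electrophiles), reduced to binary reject.

logP is the Crippen atomic-contribution estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from promiscope.ingest import ActivityProfile, Molecule

_DATA_DIR = Path(__file__).parent / "data"

DEFAULT_SIM_THRESHOLD = 0.85
DEFAULT_LOGP_THRESHOLD = 3.0

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


# ---------------------------------------------------------------------------
# PAINS catalogs


class PainsCatalog:
    """A named PAINS substructure catalog.

    Either wraps one of the public PAINS families shipped with RDKit
    (``family`` in {"A", "B", "C"}) or is loaded from a SMARTS file with one
    ``pattern_name<TAB>smarts`` entry per line.
    """

    def __init__(self, name: str, patterns: Sequence[tuple[str, Chem.Mol]]):
        self.name = name
        self._patterns = list(patterns)

    @classmethod
    def from_rdkit_family(cls, family: str) -> "PainsCatalog":
        enum = {
            "A": FilterCatalogParams.FilterCatalogs.PAINS_A,
            "B": FilterCatalogParams.FilterCatalogs.PAINS_B,
            "C": FilterCatalogParams.FilterCatalogs.PAINS_C,
        }[family.upper()]
        params = FilterCatalogParams()
        params.AddCatalog(enum)
        catalog = FilterCatalog(params)
        patterns = []
        for i in range(catalog.GetNumEntries()):
            entry = catalog.GetEntryWithIdx(i)
            # entries expose their SMARTS through the filter matcher props
            patterns.append((entry.GetDescription(), entry))
        obj = cls(f"pains_{family.lower()}", [])
        obj._catalog = catalog  # fast path: use FilterCatalog matching
        return obj

    @classmethod
    def from_smarts_file(cls, name: str, path: str | Path) -> "PainsCatalog":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"PAINS catalog file not found: {path}")
        patterns: list[tuple[str, Chem.Mol]] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pname, smarts = line.split("\t")[:2]
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"{path}: malformed SMARTS for pattern {pname!r}")
            patterns.append((pname, patt))
        return cls(name, patterns)

    def matches(self, mol: Chem.Mol) -> list[str]:
        catalog = getattr(self, "_catalog", None)
        if catalog is not None:
            return [e.GetDescription() for e in catalog.GetMatches(mol)]
        return [
            pname for pname, patt in self._patterns if mol.HasSubstructMatch(patt)
        ]


def default_pains_catalogs() -> list[PainsCatalog]:
    """The three public PAINS families (A, B, C) as three named catalogs."""
    return [PainsCatalog.from_rdkit_family(f) for f in "ABC"]


def screen_pains(
    mol: Chem.Mol | Molecule, catalogs: Sequence[PainsCatalog]
) -> dict[str, list[str]]:
    """Match a molecule against each catalog; a compound is PAINS-flagged
    iff any catalog has at least one match (it must pass all three)."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    return {cat.name: cat.matches(rdmol) for cat in catalogs}


# ---------------------------------------------------------------------------
# Aggregator likeness


class AggregatorReference:
    """Reference list of known colloidal aggregators with precomputed
    Morgan fingerprints."""

    def __init__(self, smiles_list: Sequence[str]):
        if not smiles_list:
            raise ValueError("aggregator reference list is empty")
        self.smiles = list(smiles_list)
        mols = []
        for smi in self.smiles:
            m = Chem.MolFromSmiles(smi)
            if m is None:
                raise ValueError(f"invalid aggregator reference SMILES: {smi!r}")
            mols.append(m)
        self.fps = [_MORGAN.GetFingerprint(m) for m in mols]

    @classmethod
    def from_file(cls, path: str | Path) -> "AggregatorReference":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"aggregator reference file not found: {path}")
        smiles = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles.append(line.split("\t")[0])
        return cls(smiles)

    @classmethod
    def default(cls) -> "AggregatorReference":
        return cls.from_file(_DATA_DIR / "aggregators.smi")


def calc_logp(mol: Chem.Mol | Molecule) -> float:
    """Octanol–water logP estimated as a sum of Crippen atomic
    contributions; deterministic for a given structure and invariant to the
    SMILES written form."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    return float(Crippen.MolLogP(rdmol))


def screen_aggregator(
    mol: Chem.Mol | Molecule,
    known_aggregators: AggregatorReference,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    logp_threshold: float = DEFAULT_LOGP_THRESHOLD,
) -> tuple[bool, float, float]:
    """Aggregator-likeness screen.

    Returns (flag, nearest_similarity, logp) where the flag follows the
    published advisor conjunction: nearest Tanimoto similarity to a known
    aggregator >= ``sim_threshold`` AND logP >= ``logp_threshold``.  High
    similarity alone (e.g. to a low-logP aggregator analog) does not flag.
    """
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    fp = _MORGAN.GetFingerprint(rdmol)
    nearest = max(DataStructs.TanimotoSimilarity(fp, ref) for ref in known_aggregators.fps)
    logp = calc_logp(rdmol)
    flag = nearest >= sim_threshold and logp >= logp_threshold
    return flag, float(nearest), logp


# ---------------------------------------------------------------------------
# Medicinal-chemistry rules


@dataclass(frozen=True)
class MedchemRule:
    rule_id: str
    category: str
    smarts: str
    pattern: Chem.Mol


class RuleSet:
    """Ordered list of SMARTS structural-alert rules, each with a category.

    The engine is data-driven: rule files are TSV with columns
    ``rule_id	category	smarts``; a full external rule collection can be
    dropped in without code change.  Matching is binary reject (no demerit
    scoring).
    """

    def __init__(self, rules: Sequence[MedchemRule]):
        ids = [r.rule_id for r in rules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate rule_ids in rule set")
        self.rules = list(rules)

    def __len__(self) -> int:
        return len(self.rules)

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"medchem rule file not found: {path}")
        rules = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rule_id, category, smarts = line.split("\t")[:3]
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS in rule {rule_id!r}: {smarts!r}")
            rules.append(MedchemRule(rule_id, category, smarts, patt))
        return cls(rules)

    @classmethod
    def default(cls) -> "RuleSet":
        return cls.from_file(_DATA_DIR / "medchem_rules.tsv")


def screen_medchem_rules(
    mol: Chem.Mol | Molecule, rules: RuleSet
) -> list[tuple[str, str]]:
    """Return all matching rules as (rule_id, category); a compound is
    rejected iff at least one rule matches."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    return [
        (r.rule_id, r.category)
        for r in rules.rules
        if rdmol.HasSubstructMatch(r.pattern)
    ]


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class LiabilityReport:
    """Per-compound record of every liability verdict."""

    compound_id: str
    pains_hits: dict[str, list[str]] = field(default_factory=dict)
    aggregator_flag: bool = False
    nearest_similarity: float = 0.0
    logp: float = 0.0
    medchem_violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pains_flagged(self) -> bool:
        return any(self.pains_hits.values())

    @property
    def passes_all(self) -> bool:
        return (
            not self.pains_flagged
            and not self.aggregator_flag
            and not self.medchem_violations
        )

    @property
    def causes(self) -> list[str]:
        out = []
        for cat, hits in self.pains_hits.items():
            if hits:
                out.append(f"pains:{cat}")
        if self.aggregator_flag:
            out.append("aggregator")
        for rule_id, category in self.medchem_violations:
            out.append(f"medchem:{rule_id}")
        return out


@dataclass
class FilterConfig:
    """Configuration for the full liability cascade."""

    pains_catalogs: list[PainsCatalog] = field(default_factory=default_pains_catalogs)
    aggregator_refs: AggregatorReference | None = None
    sim_threshold: float = DEFAULT_SIM_THRESHOLD
    logp_threshold: float = DEFAULT_LOGP_THRESHOLD
    medchem_rules: RuleSet | None = None

    def __post_init__(self) -> None:
        if self.aggregator_refs is None:
            self.aggregator_refs = AggregatorReference.default()
        if self.medchem_rules is None:
            self.medchem_rules = RuleSet.default()
        if len(self.pains_catalogs) != 3:
            raise ValueError("exactly three PAINS catalogs are required")


def screen_compound(
    molecule: Molecule, config: FilterConfig
) -> LiabilityReport:
    rdmol = molecule.to_rdkit()
    report = LiabilityReport(compound_id=molecule.compound_id)
    report.pains_hits = screen_pains(rdmol, config.pains_catalogs)
    flag, sim, logp = screen_aggregator(
        rdmol, config.aggregator_refs, config.sim_threshold, config.logp_threshold
    )
    report.aggregator_flag = flag
    report.nearest_similarity = sim
    report.logp = logp
    report.medchem_violations = screen_medchem_rules(rdmol, config.medchem_rules)
    return report


def apply_filter_cascade(
    profiles: Mapping[str, ActivityProfile],
    molecules: Mapping[str, Molecule],
    config: FilterConfig | None = None,
) -> tuple[dict[str, ActivityProfile], dict[str, LiabilityReport], dict[str, int]]:
    """Run the full liability cascade over a set of activity profiles.

    The passing set is the pure intersection of the three filter families
    (reordering filters never changes it); the staged counts report the
    conventional order PAINS+aggregator first, then medchem rules.

    Returns (passing profiles, per-compound reports, stage counts).
    Compounds without a resolvable structure are excluded and recorded with
    a ``missing_structure`` cause.
    """
    if config is None:
        config = FilterConfig()
    reports: dict[str, LiabilityReport] = {}
    passing: dict[str, ActivityProfile] = {}
    n_after_pains_agg = 0
    missing = 0
    for cid, profile in profiles.items():
        mol = molecules.get(cid)
        if mol is None:
            rep = LiabilityReport(compound_id=cid)
            rep.medchem_violations = [("missing_structure", "missing_structure")]
            reports[cid] = rep
            missing += 1
            continue
        rep = screen_compound(mol, config)
        reports[cid] = rep
        if not rep.pains_flagged and not rep.aggregator_flag:
            n_after_pains_agg += 1
            if not rep.medchem_violations:
                passing[cid] = profile
    counts = {
        "input": len(profiles),
        "missing_structure": missing,
        "after_pains_aggregator": n_after_pains_agg,
        "after_medchem": len(passing),
    }
    return passing, reports, counts
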