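"""Synthetic screening datasets with planted ground truth.

Every pipeline stage is testable without external downloads: the generator
emits analog series built from distinct ring-system scaffolds (so matched
molecular pairs exist within series and never across them), per-compound
tested-target sets with controlled overlap, planted promiscuity degrees
spanning 0 to >= 15, optional contradictory duplicate assay calls, and
spiked liability compounds that the PAINS / aggregator / medchem filters
must catch.

Determinism contract: the same spec (including seed) produces byte-identical
output — all sampling is integer-indexed through one ``numpy`` generator and
iteration follows fixed list order.

Each compound in a series is the scaffold with one substituent at a single
ring position (the bare scaffold is the hydrogen variant), so every
intra-series pair is a true MMP within the default size restrictions:
substituents have at most 5 heavy atoms and every scaffold core has at
least 14. Scaffolds use pairwise distinct ring systems behind a common
anilide linker; a cut isolating the shared linker fails the
core-to-substituent ratio rule, so no cross-series core can match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from promiscope.ingest import (
    ActivityProfile,
    ActivityRecord,
    Molecule,
    OUTCOME_ACTIVE,
    OUTCOME_INACTIVE,
    TargetRecord,
    standardize_molecule,
)

_ANILIDE_PREFIX = "O=C(Nc1ccccc1)"

#: distinct ring systems; ``{x}`` is the single variable substitution site
RING_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("benzene", "c2ccc{x}cc2"),
    ("pyridine2", "c2ccc{x}cn2"),
    ("pyridine3", "c2cc{x}cnc2"),
    ("pyrazine", "c2nc{x}cnc2"),
    ("pyridazine", "c2cc{x}nnc2"),
    ("thiophene", "c2cc{x}cs2"),
    ("furan", "c2cc{x}co2"),
    ("thiazole", "c2sc{x}cn2"),
    ("naphthalene", "c2ccc3ccc{x}cc3c2"),
    ("quinoline", "c2ccc3ncc{x}cc3c2"),
    ("isoquinoline", "c2cnc3ccc{x}cc3c2"),
    ("benzofuran", "c2ccc3oc{x}cc3c2"),
    ("benzothiophene", "c2ccc3sc{x}cc3c2"),
    ("indole", "c2ccc3[nH]c{x}cc3c2"),
    ("pyrimidine", "c2cc{x}ncn2"),
    ("benzoxazole", "c2ccc3nc{x}oc3c2"),
    ("benzothiazole", "c2ccc3nc{x}sc3c2"),
)

#: substituent vocabulary (<= 5 heavy atoms, liability-free); "" is hydrogen
SUBSTITUENTS: tuple[str, ...] = (
    "", "(Cl)", "(F)", "(Br)", "(I)", "(C)", "(CC)", "(CCC)", "(CCCC)",
    "(C(C)C)", "(CC(C)C)", "(C(C)(C)C)", "(CCCO)", "(OC)", "(OCC)", "(OCCC)",
    "(OC(C)C)", "(N)", "(NC)", "(N(C)C)", "(NCC)", "(C#N)", "(CO)", "(CCO)",
    "(C(C)O)", "(CN)", "(COC)", "(CCOC)", "(C(F)(F)F)", "(OC(F)(F)F)",
    "(C(=O)OC)", "(C(=O)N)", "(C(=O)NC)", "(NC(C)=O)", "(C=C)", "(CC=C)",
    "(OCC(C)C)", "(CCN)",
)

#: liability spikes: (label suffix, filter family that must flag it, SMILES)
LIABILITY_SPIKES: tuple[tuple[str, str, str], ...] = (
    ("rhodanine", "pains", "O=C1CSC(=S)N1"),
    ("ene_rhodanine", "pains", "S=C1SC(=Cc2ccccc2)C(=O)N1"),
    ("clotrimazole", "aggregator", "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1"),
    ("miconazole", "aggregator", "Clc1ccc(COC(Cn2ccnc2)c2ccc(Cl)cc2Cl)c(Cl)c1"),
    ("acyl_chloride", "medchem", "CCCCCCCC(=O)Cl"),
    ("heptanal", "medchem", "CCCCCCC=O"),
)

#: target classes with default frequencies (enzymes dominate screening
#: panels) and keyword-bearing name templates that the default class scheme
#: maps back to the planted class
_CLASS_PLAN: tuple[tuple[str, float, str, str], ...] = (
    ("Enzymes", 0.55, "serine/threonine kinase {i}", "Protein kinase family"),
    ("Receptors", 0.10, "cytokine receptor {i}", "Immune receptor family"),
    ("G protein-coupled receptors", 0.08, "orphan receptor {i}", "G protein-coupled receptor family"),
    ("Ion channels", 0.08, "voltage-gated channel {i}", "Ion channel family"),
    ("Transporters", 0.06, "solute carrier member {i}", "Solute carrier family"),
    ("Transcription factors", 0.05, "zinc finger transcription factor {i}", "Transcription factor family"),
    ("Others", 0.04, "structural protein {i}", ""),
    ("Unclassified", 0.04, "uncharacterized protein {i}", ""),
)


@dataclass
class SyntheticSpec:
    """Parameters of the planted dataset.

    Defaults are a reduced-scale model of an extensively-assayed screening
    matrix: 8 analog series of 12 compounds, 150 targets dominated by
    enzymes, tested-set sizes of 100-150 targets per compound and planted
    PD values from 0 to 18 with a census shape that decays steeply, like
    real screening panels where most compounds are consistently inactive.
    """

    seed: int = 0
    n_scaffolds: int = 8
    substituents_per_scaffold: int = 12
    n_targets: int = 150
    min_tested: int = 100
    max_tested: int | None = None  # defaults to n_targets
    conflict_rate: float = 0.0
    duplicate_rate: float = 0.05
    cliff_overlap: int = 120
    cliff_tested: int = 130
    include_liability_spikes: bool = True
    # census shape over (PD=0, PD=1, PD in 2-4, 5-9, 10-14, 15-18)
    pd_fractions: tuple[float, ...] = (0.45, 0.25, 0.15, 0.07, 0.05, 0.03)

    def __post_init__(self) -> None:
        if not 0 <= self.conflict_rate < 1:
            raise ValueError("conflict_rate must be in [0, 1)")
        if self.n_scaffolds > len(RING_TEMPLATES):
            raise ValueError(
                f"at most {len(RING_TEMPLATES)} scaffolds available"
            )
        if self.substituents_per_scaffold > len(SUBSTITUENTS):
            raise ValueError(
                f"at most {len(SUBSTITUENTS)} substituents available"
            )
        if self.substituents_per_scaffold < 2:
            raise ValueError("each series needs at least 2 compounds")
        if self.max_tested is None:
            self.max_tested = self.n_targets
        if self.max_tested > self.n_targets:
            raise ValueError("max_tested exceeds n_targets")
        if self.min_tested > self.max_tested:
            raise ValueError("min_tested exceeds max_tested")
        if self.min_tested < 18:
            # planted PD values go up to 18 and must fit into every tested set
            raise ValueError("min_tested must be at least 18 to hold planted PDs")
        if self.cliff_tested > self.n_targets or not (
            0 < self.cliff_overlap <= self.cliff_tested
        ):
            raise ValueError("invalid cliff overlap/tested sizes")
        if 2 * self.cliff_tested - self.cliff_overlap > self.n_targets:
            raise ValueError("cliff pair union exceeds the target panel")


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted truth needed to score every stage."""

    spec: SyntheticSpec
    molecules: dict[str, Molecule]
    records: list[ActivityRecord]
    targets: dict[str, TargetRecord]
    # truth tables
    compounds: pd.DataFrame  # per-compound planted values
    target_classes: dict[str, str]
    analog_pairs: set[tuple[str, str]]  # all true intra-series MMPs
    cliff_pairs: pd.DataFrame  # expected PCs among analog pairs
    conflicts: set[tuple[str, str]]  # (compound, target) with contradictory calls
    liability_labels: dict[str, str]  # spiked compound -> filter family

    def truth_pd(self) -> dict[str, int]:
        """Expected pipeline PD per compound (after conflict discarding)."""
        return dict(zip(self.compounds.compound_id, self.compounds.expected_pd))


def _target_class_plan(spec: SyntheticSpec) -> list[str]:
    """Class label per target index, by largest-remainder apportionment."""
    fracs = np.array([f for _, f, _, _ in _CLASS_PLAN])
    raw = fracs / fracs.sum() * spec.n_targets
    counts = np.floor(raw).astype(int)
    remainder = spec.n_targets - counts.sum()
    order = np.argsort(-(raw - counts))
    for k in range(remainder):
        counts[order[k]] += 1
    labels: list[str] = []
    for (label, _, _, _), c in zip(_CLASS_PLAN, counts):
        labels.extend([label] * int(c))
    return labels


def generate_targets(spec: SyntheticSpec) -> tuple[dict[str, TargetRecord], dict[str, str]]:
    """Target table with names that the default keyword scheme resolves to
    the planted classes ('Others' via explicit label)."""
    labels = _target_class_plan(spec)
    templates = {label: (pname, fname) for label, _, pname, fname in _CLASS_PLAN}
    targets: dict[str, TargetRecord] = {}
    classes: dict[str, str] = {}
    for i, label in enumerate(labels):
        tid = f"T{i:04d}"
        pname, fname = templates[label]
        explicit = label if label == "Others" else ""
        targets[tid] = TargetRecord(
            target_id=tid,
            protein_name=pname.format(i=i),
            family_name=fname,
            class_label=explicit,
        )
        classes[tid] = label
    return targets, classes


def generate_compound_series(
    spec: SyntheticSpec,
) -> tuple[dict[str, Molecule], dict[str, int], set[tuple[str, str]]]:
    """Analog series: one compound per (scaffold, substituent).

    Returns (molecules, series index per compound, true analog-pair map).
    Every intra-series unordered pair is a true MMP within the default size
    restrictions; cross-series pairs share no core.
    """
    molecules: dict[str, Molecule] = {}
    series_of: dict[str, int] = {}
    analog_pairs: set[tuple[str, str]] = set()
    idx = 0
    for s in range(spec.n_scaffolds):
        _, ring = RING_TEMPLATES[s]
        series_ids = []
        for k in range(spec.substituents_per_scaffold):
            smiles = _ANILIDE_PREFIX + ring.format(x=SUBSTITUENTS[k])
            cid = f"CPD{idx:05d}"
            idx += 1
            molecules[cid] = standardize_molecule(smiles, cid)
            series_of[cid] = s
            series_ids.append(cid)
        for i in range(len(series_ids)):
            for j in range(i + 1, len(series_ids)):
                analog_pairs.add((series_ids[i], series_ids[j]))
    return molecules, series_of, analog_pairs


def spike_liabilities(
    spec: SyntheticSpec, molecules: dict[str, Molecule]
) -> dict[str, str]:
    """Append labeled liability compounds; the label names the filter
    family that must flag each."""
    labels: dict[str, str] = {}
    if not spec.include_liability_spikes:
        return labels
    for i, (name, family, smiles) in enumerate(LIABILITY_SPIKES):
        cid = f"SPK{i:03d}_{name}"
        molecules[cid] = standardize_molecule(smiles, cid)
        labels[cid] = family
    return labels


def _sample_pd(rng: np.random.Generator, fractions: tuple[float, ...]) -> int:
    """Draw a planted PD from the census-shape categories."""
    ranges = [(0, 0), (1, 1), (2, 4), (5, 9), (10, 14), (15, 18)]
    probs = np.array(fractions, dtype=float)
    cat = int(rng.choice(len(ranges), p=probs / probs.sum()))
    lo, hi = ranges[cat]
    return int(rng.integers(lo, hi + 1))


def generate_activity_calls(
    spec: SyntheticSpec,
    molecules: dict[str, Molecule],
    series_of: dict[str, int],
    liability_labels: dict[str, str],
    target_classes: dict[str, str],
) -> tuple[list[ActivityRecord], pd.DataFrame, set[tuple[str, str]]]:
    """Emit the activity-call table and the per-compound planted truth.

    Per series, compound 0 (the hydrogen variant) is planted as a
    non-promiscuous cliff partner (PD alternating 0/1 by series) and
    compound 1 as its highly promiscuous analog with a controlled
    tested-target overlap; remaining compounds draw PD from the census
    shape.  Promiscuous compounds are multiclass by default; every third
    one stays within the enzyme class to exercise the single-class branch.
    Contradictory duplicate calls are injected pairwise at
    ``conflict_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    target_ids = sorted(target_classes)
    n = len(target_ids)
    enzyme_idx = [i for i, t in enumerate(target_ids) if target_classes[t] == "Enzymes"]
    non_enzyme_idx = [i for i, t in enumerate(target_ids) if target_classes[t] != "Enzymes"]

    ordered_cids = sorted(molecules)
    per_series: dict[int, list[str]] = {}
    for cid in ordered_cids:
        if cid in series_of:
            per_series.setdefault(series_of[cid], []).append(cid)

    # --- plant tested sets and PDs ----------------------------------------
    tested_idx: dict[str, np.ndarray] = {}
    planted_pd: dict[str, int] = {}
    single_class_flag: dict[str, bool] = {}

    promiscuous_counter = 0
    for s in sorted(per_series):
        cids = per_series[s]
        partner, promiscuous = cids[0], cids[1]
        # overlapping tested sets for the designated cliff pair
        perm = rng.permutation(n)
        nA = nB = spec.cliff_tested
        tested_idx[partner] = np.sort(perm[:nA])
        tested_idx[promiscuous] = np.sort(perm[nA - spec.cliff_overlap : nA - spec.cliff_overlap + nB])
        planted_pd[partner] = s % 2  # alternate inactive / single-target
        planted_pd[promiscuous] = int(rng.integers(10, 19))
        single_class_flag[partner] = False
        single_class_flag[promiscuous] = promiscuous_counter % 3 == 2
        promiscuous_counter += 1
        for cid in cids[2:]:
            size = int(rng.integers(spec.min_tested, spec.max_tested + 1))
            tested_idx[cid] = np.sort(rng.choice(n, size=size, replace=False))
            planted_pd[cid] = _sample_pd(rng, spec.pd_fractions)
            if planted_pd[cid] >= 10:
                single_class_flag[cid] = promiscuous_counter % 3 == 2
                promiscuous_counter += 1
            else:
                single_class_flag[cid] = bool(rng.integers(0, 2))

    # spiked liability compounds look like promiscuous frequent hitters
    for cid in sorted(liability_labels):
        size = min(spec.min_tested + 10, n)
        tested_idx[cid] = np.sort(rng.choice(n, size=size, replace=False))
        planted_pd[cid] = 12
        single_class_flag[cid] = False

    # --- choose active targets within tested sets -------------------------
    active_idx: dict[str, np.ndarray] = {}
    for cid in ordered_cids:
        t_idx = tested_idx[cid]
        k = planted_pd[cid]
        if k == 0:
            active_idx[cid] = np.array([], dtype=int)
            continue
        t_enz = np.array([i for i in t_idx if i in set(enzyme_idx)])
        t_non = np.array([i for i in t_idx if i in set(non_enzyme_idx)])
        if single_class_flag[cid] and len(t_enz) >= k:
            chosen = rng.choice(t_enz, size=k, replace=False)
        elif k >= 2 and len(t_non) >= 1 and len(t_enz) >= 1:
            # force a multiclass spread: at least one enzyme + one non-enzyme
            first = rng.choice(t_enz, size=1)
            second = rng.choice(t_non, size=1)
            rest_pool = np.setdiff1d(t_idx, np.concatenate([first, second]))
            rest = rng.choice(rest_pool, size=k - 2, replace=False)
            chosen = np.concatenate([first, second, rest])
        else:
            chosen = rng.choice(t_idx, size=k, replace=False)
        active_idx[cid] = np.sort(chosen)

    # --- emit records with duplicates and conflicts -----------------------
    records: list[ActivityRecord] = []
    conflicts: set[tuple[str, str]] = set()
    assay_counter = 0

    def next_assay() -> str:
        nonlocal assay_counter
        assay_counter += 1
        return f"A{assay_counter:06d}"

    for cid in ordered_cids:
        actives = set(active_idx[cid].tolist())
        for i in tested_idx[cid].tolist():
            tid = target_ids[i]
            outcome = OUTCOME_ACTIVE if i in actives else OUTCOME_INACTIVE
            records.append(ActivityRecord(cid, next_assay(), tid, outcome))
            u = rng.random()
            if u < spec.conflict_rate:
                flipped = (
                    OUTCOME_INACTIVE if outcome == OUTCOME_ACTIVE else OUTCOME_ACTIVE
                )
                records.append(ActivityRecord(cid, next_assay(), tid, flipped))
                conflicts.add((cid, tid))
            elif u < spec.conflict_rate + spec.duplicate_rate:
                records.append(ActivityRecord(cid, next_assay(), tid, outcome))

    # --- truth table -------------------------------------------------------
    rows = []
    for cid in ordered_cids:
        t_ids = {target_ids[i] for i in tested_idx[cid].tolist()}
        a_ids = {target_ids[i] for i in active_idx[cid].tolist()}
        conf = {t for (c, t) in conflicts if c == cid}
        exp_tested = t_ids - conf
        exp_active = a_ids - conf
        exp_classes = {target_classes[t] for t in exp_active}
        rows.append(
            {
                "compound_id": cid,
                "smiles": molecules[cid].smiles,
                "series": series_of.get(cid, -1),
                "planted_pd": planted_pd[cid],
                "planted_n_tested": len(t_ids),
                "expected_pd": len(exp_active),
                "expected_n_tested": len(exp_tested),
                "n_conflicted": len(conf),
                "expected_n_active_classes": len(exp_classes),
                "expected_multiclass": len(exp_active) >= 10 and len(exp_classes) >= 2,
                "liability": liability_labels.get(cid, ""),
            }
        )
    truth = pd.DataFrame(rows)
    return records, truth, conflicts


def _expected_cliffs(
    truth: pd.DataFrame,
    analog_pairs: set[tuple[str, str]],
    records: list[ActivityRecord],
    conflicts: set[tuple[str, str]],
    pd_hi: int = 10,
    pd_lo: int = 1,
) -> pd.DataFrame:
    """All analog pairs expected to surface as promiscuity cliffs, with the
    expected shared-tested counts, derived from the planted truth alone."""
    tested: dict[str, set[str]] = {}
    for rec in records:
        tested.setdefault(rec.compound_id, set()).add(rec.target_id)
    for cid, tid in conflicts:
        tested[cid].discard(tid)
    exp_pd = dict(zip(truth.compound_id, truth.expected_pd))
    rows = []
    for a, b in sorted(analog_pairs):
        pa, pb = exp_pd[a], exp_pd[b]
        for (hi, lo, pd_h, pd_l) in ((a, b, pa, pb), (b, a, pb, pa)):
            if pd_h >= pd_hi and pd_l <= pd_lo:
                rows.append(
                    {
                        "promiscuous_id": hi,
                        "partner_id": lo,
                        "pd_promiscuous": pd_h,
                        "pd_partner": pd_l,
                        "shared_tested": len(tested[hi] & tested[lo]),
                    }
                )
                break
    return pd.DataFrame(
        rows,
        columns=[
            "promiscuous_id",
            "partner_id",
            "pd_promiscuous",
            "pd_partner",
            "shared_tested",
        ],
    )


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate the full planted dataset (molecules, calls, targets, truth)."""
    if spec is None:
        spec = SyntheticSpec()
    targets, target_classes = generate_targets(spec)
    molecules, series_of, analog_pairs = generate_compound_series(spec)
    liability_labels = spike_liabilities(spec, molecules)
    records, truth, conflicts = generate_activity_calls(
        spec, molecules, series_of, liability_labels, target_classes
    )
    cliff_pairs = _expected_cliffs(truth, analog_pairs, records, conflicts)
    return SyntheticDataset(
        spec=spec,
        molecules=molecules,
        records=records,
        targets=targets,
        compounds=truth,
        target_classes=target_classes,
        analog_pairs=analog_pairs,
        cliff_pairs=cliff_pairs,
        conflicts=conflicts,
        liability_labels=liability_labels,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the input TSV dialects the ingest module reads, plus truth
    tables sufficient to score every stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(m.compound_id, m.smiles) for m in ds.molecules.values()],
        columns=["compound_id", "smiles"],
    ).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.compound_id, r.assay_id, r.target_id, r.outcome) for r in ds.records],
        columns=["compound_id", "assay_id", "target_id", "outcome"],
    ).to_csv(outdir / "activities.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (t.target_id, t.protein_name, t.family_name, t.class_label)
            for t in ds.targets.values()
        ],
        columns=["target_id", "protein_name", "family_name", "class_label"],
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    ds.compounds.to_csv(outdir / "truth_compounds.tsv", sep="\t", index=False)
    ds.cliff_pairs.to_csv(outdir / "truth_cliffs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.analog_pairs), columns=["compound_a", "compound_b"]
    ).to_csv(outdir / "truth_analog_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.conflicts), columns=["compound_id", "target_id"]
    ).to_csv(outdir / "truth_conflicts.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hand-constructed worked example


def worked_example() -> tuple[dict[str, Molecule], dict[str, ActivityProfile]]:
    """A canonical two-compound cliff fixture.

    Compound WE_PROM carries one chlorine that WE_PART lacks; WE_PROM was
    tested on 178 targets and active on 34, WE_PART on 195 targets with no
    activity, and the two tested sets share 170 targets.  Exactly one
    promiscuity cliff with shared_tested = 170 and PDs (34, 0) must result.
    """
    prom = standardize_molecule(_ANILIDE_PREFIX + "c2ccc(Cl)cc2", "WE_PROM")
    part = standardize_molecule(_ANILIDE_PREFIX + "c2ccccc2", "WE_PART")
    tids = [f"T{i:03d}" for i in range(203)]
    tested_a = frozenset(tids[:178])
    tested_b = frozenset(tids[8:203])  # overlap with tested_a: indices 8..177
    active_a = frozenset(tids[:34])
    profiles = {
        "WE_PROM": ActivityProfile("WE_PROM", tested_a, active_a),
        "WE_PART": ActivityProfile("WE_PART", tested_b, frozenset()),
    }
    return {"WE_PROM": prom, "WE_PART": part}, profiles
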