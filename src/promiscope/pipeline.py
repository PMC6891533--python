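"""End-to-end orchestration and deposition-style reporting.

``run_pipeline`` wires the stages together — ingest, liability filtering,
promiscuity census, target classes, MMP/cliff detection, cliff network —
and writes TSV artifacts plus a machine-readable run summary with the
staged-attrition accounting (how many compounds each stage admitted).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from promiscope import filters as flt
from promiscope import ingest, mmp as mmpmod, network as netmod
from promiscope import promiscuity as promod
from promiscope import target_classes as tcmod
from promiscope.ingest import ActivityProfile, Molecule

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds, paths and stage toggles for one pipeline run."""

    input_dir: str = "."
    output_dir: str = "out"
    min_tested: int = 100
    pd_hi: int = 10
    pd_lo: int = 1
    hub_min_degree: int = 10
    hub_mode: str = "fixed"
    path_min_length: int = 3
    max_paths: int = 10_000
    seed: int = 0
    # size restrictions
    max_substituent_heavy_atoms: int = 13
    min_core_to_substituent_ratio: float = 2.0
    max_transformation_difference_heavy_atoms: int = 8
    # filter settings (None = shipped defaults)
    pains_catalog_files: list[str] | None = None
    aggregator_file: str | None = None
    medchem_rules_file: str | None = None
    sim_threshold: float = flt.DEFAULT_SIM_THRESHOLD
    logp_threshold: float = flt.DEFAULT_LOGP_THRESHOLD
    class_scheme_file: str | None = None
    # stage toggles
    do_filters: bool = True
    do_classes: bool = True
    do_cliffs: bool = True
    do_network: bool = True

    def __post_init__(self) -> None:
        if self.min_tested < 1 or self.pd_hi < 1 or self.hub_min_degree < 1:
            raise ValueError("thresholds must be positive")
        if self.pd_lo >= self.pd_hi:
            raise ValueError("pd_lo must be smaller than pd_hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def restrictions(self) -> mmpmod.SizeRestrictions:
        return mmpmod.SizeRestrictions(
            self.max_substituent_heavy_atoms,
            self.min_core_to_substituent_ratio,
            self.max_transformation_difference_heavy_atoms,
        )

    def filter_config(self) -> flt.FilterConfig:
        if self.pains_catalog_files:
            if len(self.pains_catalog_files) != 3:
                raise ValueError("exactly three PAINS catalog files required")
            catalogs = [
                flt.PainsCatalog.from_smarts_file(Path(p).stem, p)
                for p in self.pains_catalog_files
            ]
        else:
            catalogs = flt.default_pains_catalogs()
        refs = (
            flt.AggregatorReference.from_file(self.aggregator_file)
            if self.aggregator_file
            else flt.AggregatorReference.default()
        )
        rules = (
            flt.RuleSet.from_file(self.medchem_rules_file)
            if self.medchem_rules_file
            else flt.RuleSet.default()
        )
        return flt.FilterConfig(
            pains_catalogs=catalogs,
            aggregator_refs=refs,
            sim_threshold=self.sim_threshold,
            logp_threshold=self.logp_threshold,
            medchem_rules=rules,
        )

    def class_scheme(self) -> tcmod.ClassScheme:
        if self.class_scheme_file:
            return tcmod.ClassScheme.from_yaml(self.class_scheme_file)
        return tcmod.ClassScheme.default()


# ---------------------------------------------------------------------------
# profile (de)serialization so CLI stages can hand results to each other


def write_profiles(
    profiles: Mapping[str, ActivityProfile], path: str | Path
) -> None:
    rows = [
        (
            p.compound_id,
            ";".join(sorted(p.tested_targets)),
            ";".join(sorted(p.active_targets)),
            ";".join(sorted(p.discarded_targets)),
        )
        for p in profiles.values()
    ]
    pd.DataFrame(
        rows,
        columns=["compound_id", "tested_targets", "active_targets", "discarded_targets"],
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, ActivityProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for r in df.itertuples(index=False):
        split = lambda s: frozenset(x for x in s.split(";") if x)  # noqa: E731
        out[r.compound_id] = ActivityProfile(
            r.compound_id,
            split(r.tested_targets),
            split(r.active_targets),
            split(r.discarded_targets),
        )
    return out


def export_multiclass_ligands(
    class_profiles: Mapping[str, tcmod.ClassProfile],
    profiles: Mapping[str, ActivityProfile],
    molecules: Mapping[str, Molecule],
    path: str | Path,
) -> int:
    """Deposition-style table of multiclass ligands: exactly four columns —
    compound id, SMILES, PD, number of tested targets — sorted by
    descending PD then id.  Returns the number of rows written."""
    rows = []
    for cid, cp in class_profiles.items():
        if cp.is_multiclass:
            rows.append(
                (cid, molecules[cid].smiles, profiles[cid].pd, profiles[cid].n_tested)
            )
    rows.sort(key=lambda r: (-r[2], r[0]))
    pd.DataFrame(rows, columns=["compound_id", "smiles", "pd", "n_tested"]).to_csv(
        path, sep="\t", index=False
    )
    return len(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute ingest -> filters -> promiscuity -> classes -> MMP/cliffs ->
    network -> reports and return the machine-readable run summary."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    # --- ingest ------------------------------------------------------------
    molecules, rejected = ingest.read_compounds(indir / "compounds.tsv")
    ingest.write_rejects(rejected, outdir / "rejected.tsv")
    records = ingest.read_activities(indir / "activities.tsv")
    targets = ingest.read_targets(indir / "targets.tsv")
    profiles = ingest.aggregate_profiles(records)
    extensively = ingest.select_extensively_tested(profiles, config.min_tested)
    write_profiles(extensively, outdir / "profiles.tsv")
    summary["stages"]["ingest"] = {
        "compounds_in": len(molecules) + len(rejected),
        "compounds_standardized": len(molecules),
        "compounds_rejected": len(rejected),
        "activity_records": len(records),
        "profiles": len(profiles),
        "extensively_tested": len(extensively),
    }

    # --- liability filters ---------------------------------------------------
    if config.do_filters:
        passing, reports, counts = flt.apply_filter_cascade(
            extensively, molecules, config.filter_config()
        )
        rep_rows = [
            (
                cid,
                ";".join(r.causes),
                f"{r.nearest_similarity:.4f}",
                f"{r.logp:.4f}",
                int(r.passes_all),
            )
            for cid, r in sorted(reports.items())
        ]
        pd.DataFrame(
            rep_rows,
            columns=["compound_id", "causes", "nearest_similarity", "logp", "passes_all"],
        ).to_csv(outdir / "liability_reports.tsv", sep="\t", index=False)
        summary["stages"]["filters"] = counts
    else:
        passing = dict(extensively)
        summary["stages"]["filters"] = {"skipped": True, "passing": len(passing)}
    write_profiles(passing, outdir / "passing_profiles.tsv")

    # --- promiscuity ---------------------------------------------------------
    census = promod.pd_census(passing)
    pd.DataFrame(
        [(b.label, census.counts[b.label]) for b in census.bins],
        columns=["bin", "count"],
    ).to_csv(outdir / "census.tsv", sep="\t", index=False)
    dists = promod.tested_distribution_by_pd(passing)
    _write_distributions(dists, outdir / "distributions.tsv")
    logp_dists = promod.logp_distribution_by_pd(passing, molecules)
    _write_distributions(logp_dists, outdir / "logp_distributions.tsv")
    summary["stages"]["promiscuity"] = {"census": census.counts}

    # --- target classes -----------------------------------------------------
    class_profiles: dict[str, tcmod.ClassProfile] = {}
    if config.do_classes:
        scheme = config.class_scheme()
        table = tcmod.class_table(targets, scheme)
        pd.DataFrame(
            sorted(table.items()), columns=["target_class", "n_targets"]
        ).to_csv(outdir / "class_table.tsv", sep="\t", index=False)
        class_profiles = {
            cid: tcmod.class_profile(p, targets, scheme, config.pd_hi)
            for cid, p in passing.items()
        }
        n_multi = export_multiclass_ligands(
            class_profiles, passing, molecules, outdir / "multiclass_ligands.tsv"
        )
        hist = tcmod.class_count_histogram(class_profiles.values(), config.pd_hi)
        single = tcmod.single_class_promiscuous(class_profiles.values())
        summary["stages"]["classes"] = {
            "class_table": table,
            "multiclass_ligands": n_multi,
            "class_count_histogram": {str(k): v for k, v in sorted(hist.items())},
            "single_class_promiscuous": len(single),
        }

    # --- MMPs and cliffs ----------------------------------------------------
    cliffs: list[mmpmod.PromiscuityCliff] = []
    if config.do_cliffs:
        passing_mols = {cid: molecules[cid] for cid in passing if cid in molecules}
        mmps = mmpmod.find_mmps(passing_mols, config.restrictions())
        pd.DataFrame(
            [
                (m.compound_a, m.compound_b, m.core, m.transformation)
                for m in mmps
            ],
            columns=["compound_a", "compound_b", "core", "transformation"],
        ).to_csv(outdir / "mmps.tsv", sep="\t", index=False)
        cliffs = mmpmod.detect_promiscuity_cliffs(
            mmps, passing, config.pd_hi, config.pd_lo
        )
        pd.DataFrame(
            [
                (
                    c.promiscuous_id,
                    c.partner_id,
                    c.pd_promiscuous,
                    c.pd_partner,
                    c.mmp.transformation,
                    c.shared_tested,
                )
                for c in cliffs
            ],
            columns=[
                "promiscuous_id",
                "partner_id",
                "pd_promiscuous",
                "pd_partner",
                "transformation",
                "shared_tested",
            ],
        ).to_csv(outdir / "cliffs.tsv", sep="\t", index=False)
        summary["stages"]["cliffs"] = {"mmps": len(mmps), "cliffs": len(cliffs)}

    # --- network ------------------------------------------------------------
    if config.do_network and config.do_cliffs:
        multiclass_ids = (
            {cid for cid, cp in class_profiles.items() if cp.is_multiclass}
            if class_profiles
            else None
        )
        net = netmod.build_pc_network(cliffs, multiclass_ids=multiclass_ids)
        nx.write_graphml(net.graph, outdir / "network.graphml")
        pd.DataFrame(
            [
                (u, v, d["transformation"], d["shared_tested"])
                for u, v, d in net.graph.edges(data=True)
            ],
            columns=["compound_a", "compound_b", "transformation", "shared_tested"],
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        hubs = netmod.find_promiscuity_hubs(
            net, config.hub_min_degree, config.hub_mode
        )
        pd.DataFrame(sorted(hubs), columns=["compound_id"]).to_csv(
            outdir / "hubs.tsv", sep="\t", index=False
        )
        pathways = netmod.extract_pathways(
            net, config.path_min_length, config.max_paths
        )
        pd.DataFrame(
            [(i, ";".join(p.nodes), len(p)) for i, p in enumerate(pathways)],
            columns=["path_id", "nodes", "n_nodes"],
        ).to_csv(outdir / "pathways.tsv", sep="\t", index=False)
        summary["stages"]["network"] = {
            "nodes": net.n_nodes,
            "edges": net.n_edges,
            "components": len(net.components()),
            "hubs": len(hubs),
            "pathways": len(pathways),
        }

    summary["config"] = asdict(config)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_distributions(
    dists: Mapping[str, promod.DistributionSummary], path: Path
) -> None:
    pd.DataFrame(
        [
            (d.group, d.n, d.min, d.q1, d.median, d.q3, d.max)
            for d in dists.values()
        ],
        columns=["group", "n", "min", "q1", "median", "q3", "max"],
    ).to_csv(path, sep="\t", index=False)
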