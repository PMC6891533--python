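# promiscope

Compound promiscuity analysis from qualitative screening data.

Large biological screening collections report, for each compound–target
pair, only a binary call: active or inactive. When a compound has been
tested against enough distinct targets, those calls support a simple but
powerful statistic — the **promiscuity degree** (PD), the number of targets
the compound is active against — and, from there, the identification of
**multiclass ligands** (PD ≥ 10 with activity spanning at least two target
classes), the compounds most interesting for polypharmacology. promiscope
implements that analysis as a reusable pipeline for computational chemists
working with screening matrices:

1. **Ingest** — structures are standardized (largest organic fragment,
   charge neutralization, canonical SMILES); repeated assay calls for the
   same compound–target pair must agree, otherwise the pair is discarded;
   only compounds tested against ≥ 100 distinct targets are kept.
2. **Liability filtering** — promiscuity analysis is uniquely vulnerable to
   false positives (one frequent hitter looks like a genuine multitarget
   ligand), so compounds must pass three PAINS substructure catalogs, an
   aggregator-likeness screen (Tanimoto ≥ 0.85 to a known colloidal
   aggregator **and** Crippen logP ≥ 3), and a medicinal-chemistry
   structural-alert rule engine.
3. **Promiscuity profiling** — PD census over exact and nested bins
   (PD=0, PD=1, PD≥2, ≥5, ≥10, ≥15), boxplot summaries of test frequencies
   per PD bin and of logP per promiscuity stratum.
4. **Target classes** — targets map to eight classes (Enzymes, GPCRs,
   Transcription factors, Ion channels, Receptors, Transporters, Others,
   Unclassified) by ordered keyword rules; multiclass ligands and
   single-class promiscuous compounds are derived per compound.
5. **Promiscuity cliffs** — matched molecular pairs (MMPs: two compounds
   differing by a single-site substituent exchange over an identical core,
   found by single-cut fragmentation with size restrictions) are scanned
   for **promiscuity cliffs** (PCs): an MMP joining a PD ≥ 10 compound to a
   PD ≤ 1 analog, annotated with the number of shared tested targets.
6. **Cliff network** — compounds as nodes, PCs as edges; the graph is
   bipartite by construction. Promiscuity hubs are multiclass ligands with
   ≥ 10 cliff relationships; pathways are maximal simple paths alternating
   between promiscuous and non-promiscuous analogs.

A fully deterministic synthetic-data generator plants analog series,
PD values, class spreads, call conflicts and liability spikes with known
ground truth, so every stage is testable end to end without downloads.

## Worked example

Generate a small planted dataset (4 analog series × 6 substituents plus 6
spiked liability compounds) and run the full pipeline:

```bash
promiscope simulate --seed 5 --scaffolds 4 --substituents 6 --out demo_in
promiscope run-all --input-dir demo_in --output-dir demo_out
```

The run summary reports the staged attrition and per-stage results:

```
"filters":     {"input": 30, "after_pains_aggregator": 26, "after_medchem": 24}
"promiscuity": {"census": {"all": 24, "PD=0": 11, "PD=1": 7, "PD>=2": 6,
                           "PD>=5": 5, "PD>=10": 4, "PD>=15": 2}}
"classes":     {"multiclass_ligands": 3, "single_class_promiscuous": 3}
"cliffs":      {"mmps": 60, "cliffs": 18}
"network":     {"nodes": 22, "edges": 18, "components": 4, "pathways": 32}
```

All 30 compounds are extensively tested; the six spiked liability compounds
are removed by the filter cascade (30 → 26 → 24), the 24 survivors
distribute over the PD census bins exactly as planted, and 60 MMPs yield 18
promiscuity cliffs. `demo_out/cliffs.tsv` shows each cliff with its
transformation and confidence:

```
promiscuous_id  partner_id  pd_promiscuous  pd_partner  transformation  shared_tested
CPD00001        CPD00000    12              0           [*][H]>>*Cl     120
CPD00001        CPD00002    12              0           *Cl>>*F         109
```

— the first line reads: adding one chlorine to the consistently inactive
CPD00000 gives its analog CPD00001, active against 12 targets, with the two
compounds sharing 120 tested targets. The deposition-style
`multiclass_ligands.tsv` lists each multiclass ligand as
`compound_id  smiles  pd  n_tested`, sorted by descending PD.

The same stages are available as individual CLI verbs (`ingest`, `filter`,
`profile`, `cliffs`, `network`, `report`) operating on a workspace
directory, and as plain library functions (`aggregate_profiles`,
`apply_filter_cascade`, `find_mmps`, `detect_promiscuity_cliffs`,
`build_pc_network`, ...).

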