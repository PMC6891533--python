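# Methods

## The promiscuity model

promiscope works entirely on qualitative screening calls. The unit of
evidence is one assay call `(compound, assay, target, active|inactive)`;
potency values are deliberately ignored because qualitative screens rarely
report comparable ones. Aggregation reduces calls to one of three states
per compound–target pair: *active* (all calls active), *tested-inactive*
(all calls inactive), or *discarded* (contradictory calls). Discarded pairs
count neither as tested nor as active, so they also do not help a compound
over the extensively-tested threshold. The promiscuity degree is then
simply PD = |active targets|. This makes PD estimates conservative in two
directions: conflicts are thrown away rather than resolved by majority, and
the ≥ 100-tested-targets filter (configurable `min_tested`) guards against
PD values driven by sparse testing.

A multiclass ligand is a compound with PD ≥ `pd_hi` (default 10) whose
active targets span at least two of the eight target classes. The
complementary set — highly promiscuous compounds confined to one class —
and the broader single-class promiscuous set (PD ≥ 2, one class) partition
the promiscuous compounds exactly; this partition is asserted in tests.

## Liability filtering

The three filter families are independent verdicts and the passing set is
their intersection, so family order can only change staged counts, never
the outcome (a property test permutes the order). Choices worth noting:

* **PAINS** — the three shipped catalogs are the public PAINS families A,
  B and C as distributed with RDKit. The pass-all-three policy is the
  semantic core; any three SMARTS files can be substituted via config.
* **Aggregator screen** — the published advisor logic is a conjunction:
  nearest Tanimoto similarity ≥ 0.85 (Morgan fingerprint, radius 2,
  2048 bits) to a known aggregator AND Crippen logP ≥ 3. Similarity alone
  never flags. The shipped reference list is a small curated fixture of
  well-documented colloidal aggregators; a production run should point
  `aggregator_refs` at a full reference collection.
* **Medchem rules** — a data-driven SMARTS rule engine with categories
  (acylating agents, aldehydes, chelators, reactive electrophiles,
  quinones, nitro compounds, peroxides, azides, thiols, hydrazines). The
  shipped file is a representative subset, not a complete alert
  collection; scoring is binary reject because the pipeline only uses
  rules for exclusion. Both thresholds and all rule/catalog files are
  config keys.

logP is the Crippen atomic-contribution estimate throughout (the methane
value is checked against a hand-summed contribution table in the tests).

## MMP fragmentation and promiscuity cliffs

Single-cut fragmentation breaks each acyclic single bond between heavy
atoms; additionally every hydrogen position yields a (whole molecule,
H-substituent) decomposition so H→Cl or H→CH3 exchanges are discoverable.
Fragments carry one wildcard attachment point and are compared by
canonical-SMILES string equality, which makes MMP search an exact-match
grouping problem. Size restrictions (defaults: substituent ≤ 13 heavy
atoms, core ≥ 2× substituent, exchanged substituents differing by ≤ 8
heavy atoms) are applied per fragmentation and per pair. When a pair
matches on several cores, the largest core — i.e. the smallest
transformation — is kept, with a lexicographic tie-break on
(core, transformation) for determinism; each unordered pair therefore
appears at most once. The index-based search is tested for exact
equivalence against a quadratic all-pairs oracle.

A promiscuity cliff requires one member at PD ≥ `pd_hi` (10) and the other
at PD ≤ `pd_lo` (1); both thresholds are inclusive boundaries and are
config-exposed. `shared_tested = |tested_a ∩ tested_b|` is carried as a
confidence annotation: a cliff whose members were tested on largely
disjoint panels would be weak evidence of a real promiscuity difference.

## Cliff network

Nodes are compounds, edges are cliffs, and bipartiteness (promiscuous side
vs partner side) is checked at construction, not assumed — a compound
appearing on both sides indicates an upstream bug and raises. Hubs use the
fixed rule (multiclass ligand with degree ≥ 10) as primary; an
above-average-degree mode exists as an alternative because the two
formulations circulate in the field. Pathways are *maximal* simple paths
(neither endpoint extendable), enumerated depth-first with sorted neighbor
order, orientation-deduplicated, and capped (`max_paths`, default 10 000)
because dense complete-bipartite cliff clusters have combinatorially many
paths. Maximality was chosen over fixed-length curation as the more
reproducible definition.

## Synthetic data: what it emulates and what it does not

The generator plants every feature the pipeline measures:

* **Analog series** — 17 available scaffolds, each a distinct ring system
  behind a common anilide linker, each series varying one substitution
  site over a ≤ 5-heavy-atom vocabulary (hydrogen included). Every
  intra-series pair is a true MMP within the default restrictions; the
  shared linker cannot produce cross-series cores because a cut isolating
  it fails the core-to-substituent ratio rule. Scaffolds must be pairwise
  non-analogous for this guarantee — an earlier draft that included both
  indole and N-methylindole violated it (the two differ by one methyl on
  the ring nitrogen, a genuine MMP), so ring systems are required to
  differ by more than a substituent exchange.
* **Screening matrix** — 150 targets by default (eight classes, enzymes at
  55%, mirroring the enzyme-heavy composition of public screening panels),
  tested-set sizes uniform between 100 and 150. This is a deliberate
  reduced-scale model: real extensively-tested collections have hundreds
  of thousands of compounds with median test frequencies around 200–240
  targets; defaults here (96 compounds; 510 in the acceptance runs) keep
  full runs in seconds while preserving every structural property under
  test. Sizes are config, not constants.
* **Planted PDs** — census shape (45% PD=0, 25% PD=1, 15% PD 2–4, 7%
  PD 5–9, 5% PD 10–14, 3% PD 15–18) decaying steeply as in real panels.
  Each series additionally plants one designated cliff pair — a PD ≤ 1
  partner and a PD ≥ 10 analog — with a controlled tested-set overlap
  (default 120 of 130), so cliff recovery and `shared_tested` are exactly
  predictable. Promiscuous compounds are multiclass by default; every
  third stays within the enzyme class to exercise the single-class branch.
* **Noise** — contradictory duplicate calls at `conflict_rate` and
  consistent duplicates at `duplicate_rate` (5%). The truth table records
  both planted and post-conflict expected values, so recovery is scored
  without re-deriving truth. No other noise model is included: there are
  no correlated assay batch effects, no target-family activity
  correlations, and no false calls that *agree* with each other —
  consistent wrong calls are invisible to the consistency rule by design,
  in synthetic and real data alike. Passing tests therefore demonstrate
  bookkeeping correctness and algorithmic exactness, not robustness to
  systematic assay error.
* **Liability spikes** — six labeled compounds (two PAINS cores, two known
  aggregators, an acyl chloride, an aliphatic aldehyde), each verified to
  trip exactly the filter family its label names; all scaffold/substituent
  combinations are verified clean, so the filter confusion matrix has an
  exact expected value (100% spike exclusion, 0% decoy exclusion).

Determinism: one `numpy` generator seeded from the spec drives all
sampling, iteration is over sorted or index-ordered containers, and
byte-identical output under a fixed seed is a tested contract.

## Numerical conventions and degenerate inputs

* Quartiles: linear interpolation between order statistics (numpy's
  `method="linear"`); recorded in each summary's metadata since
  conventions differ between tools. Outliers: beyond 1.5×IQR whiskers.
  Empty groups produce an n=0 summary with NaN statistics rather than an
  error; a single value collapses min=q1=median=q3=max.
* Census bins mix exact (PD=0, PD=1) and nested threshold bins; the
  conservation identity (PD=0 + PD=1 + PD≥2 = all) and threshold nesting
  are validated at construction and property-tested on arbitrary inputs.
* Kernel density curves for logP strata (Gaussian kernel, Scott's rule)
  are cosmetic plotting output and carry no analytical weight; they are
  skipped for strata with fewer than three points or zero variance.
* Standardization keeps the largest organic fragment, neutralizes simple
  charges and canonicalizes the tautomer as given (no tautomer
  enumeration) — idempotent by construction and tested. Unparseable
  SMILES raise a typed error carrying the offending input; table readers
  convert these into logged rejection rows, never silent drops.
* Targets with an explicit class label bypass keyword rules entirely;
  "Others" can only be assigned this way. Keyword rules are ordered,
  first match wins, specific before generic ("G protein-coupled
  receptor" and "nuclear receptor" before the bare "receptor" fallback).

## Known limitations

* Single-cut MMPs only; multi-cut transformations and matched molecular
  series are out of scope.
* The aggregator screen is a similarity heuristic, not an aggregation
  prediction; with the small shipped reference list its recall on real
  aggregators is limited by reference coverage.
* The shipped medchem rule file is a representative subset; absolute
  filter attrition numbers on real data depend entirely on the rule and
  catalog collections supplied.
* Keyword-based target classification is shallow: it has no ontology
  hierarchy and inherits whatever naming conventions the target table
  uses.
* Pathway enumeration is exponential in dense cliff clusters; the cap
  makes output deterministic but necessarily partial on such graphs.
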