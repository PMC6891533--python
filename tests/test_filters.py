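"""Liability screens: PAINS catalogs, aggregator heuristic, medchem rules."""

import itertools

import pytest
from rdkit import Chem

from promiscope.filters import (
    AggregatorReference,
    FilterConfig,
    LiabilityReport,
    RuleSet,
    apply_filter_cascade,
    calc_logp,
    screen_aggregator,
    screen_medchem_rules,
    screen_pains,
)
from promiscope.ingest import ActivityProfile, standardize_molecule

RHODANINE = "O=C1CSC(=S)N1"
CLOTRIMAZOLE = "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1"


def _mol(smiles):
    return Chem.MolFromSmiles(smiles)


class TestPains:
    def test_rhodanine_core_flagged_by_at_least_one_catalog(self, filter_config):
        hits = screen_pains(_mol(RHODANINE), filter_config.pains_catalogs)
        assert any(hits.values())

    def test_ethanol_matches_no_catalog(self, filter_config):
        hits = screen_pains(_mol("CCO"), filter_config.pains_catalogs)
        assert not any(hits.values())

    def test_single_catalog_match_fails_pass_all_policy(self, filter_config):
        # the saturated rhodanine core hits exactly one of the three families
        hits = screen_pains(_mol(RHODANINE), filter_config.pains_catalogs)
        n_matching = sum(1 for v in hits.values() if v)
        assert n_matching == 1
        report = LiabilityReport("x", pains_hits=hits)
        assert not report.passes_all


class TestAggregator:
    def test_identity_to_known_aggregator_with_high_logp_flags(self, filter_config):
        flag, sim, logp = screen_aggregator(
            _mol(CLOTRIMAZOLE), filter_config.aggregator_refs
        )
        assert flag and sim == pytest.approx(1.0) and logp >= 3.0

    def test_similarity_below_threshold_does_not_flag(self, filter_config):
        flag, sim, _ = screen_aggregator(
            _mol("CCO"), filter_config.aggregator_refs
        )
        assert sim < 0.85 and not flag

    def test_threshold_boundary_is_inclusive(self):
        refs = AggregatorReference(["CCCCCCCCCCCC"])  # logP-rich reference
        mol = _mol("CCCCCCCCCCCC")
        flag, sim, logp = screen_aggregator(mol, refs, sim_threshold=1.0)
        assert sim == pytest.approx(1.0) and logp >= 3.0 and flag

    def test_high_similarity_but_low_logp_does_not_flag(self):
        # advisor logic is a conjunction: similarity alone never flags
        refs = AggregatorReference(["CCO"])
        flag, sim, logp = screen_aggregator(_mol("CCO"), refs)
        assert sim == pytest.approx(1.0)
        assert logp < 3.0
        assert not flag

    def test_empty_reference_list_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            AggregatorReference([])


class TestMedchemRules:
    def test_acyl_chloride_violates_acylating_agent_category(self, filter_config):
        violations = screen_medchem_rules(
            _mol("CCCCCCCC(=O)Cl"), filter_config.medchem_rules
        )
        assert ("acyl_halide", "acylating_agents") in violations

    def test_aliphatic_aldehyde_violates_aldehyde_category(self, filter_config):
        violations = screen_medchem_rules(
            _mol("CCCCCCC=O"), filter_config.medchem_rules
        )
        assert any(cat == "aldehydes" for _, cat in violations)

    def test_benzamide_is_clean(self, filter_config):
        assert screen_medchem_rules(
            _mol("NC(=O)c1ccccc1"), filter_config.medchem_rules
        ) == []

    def test_malformed_smarts_is_a_hard_error_naming_the_rule(self, tmp_path):
        f = tmp_path / "rules.tsv"
        f.write_text("bad_rule\tsome_category\t[[[\n")
        with pytest.raises(ValueError, match="bad_rule"):
            RuleSet.from_file(f)

    def test_missing_rule_file_is_a_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RuleSet.from_file(tmp_path / "nope.tsv")


class TestLogP:
    def test_methane_equals_hand_summed_atomic_contributions(self):
        # one sp3 carbon (0.1441) + four carbon-attached hydrogens (0.1230)
        assert calc_logp(_mol("C")) == pytest.approx(0.1441 + 4 * 0.1230, abs=1e-4)

    def test_each_methylene_adds_a_positive_contribution(self):
        alkanes = ["C" * n for n in range(3, 9)]
        values = [calc_logp(_mol(s)) for s in alkanes]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_invariant_to_smiles_writing(self):
        assert calc_logp(_mol("OCC")) == pytest.approx(calc_logp(_mol("CCO")))


class TestCascade:
    @staticmethod
    def _profiles_and_mols(entries):
        profiles, molecules = {}, {}
        targets = frozenset(f"T{i}" for i in range(100))
        for cid, smiles in entries.items():
            profiles[cid] = ActivityProfile(cid, targets, frozenset())
            molecules[cid] = standardize_molecule(smiles, cid)
        return profiles, molecules

    def test_aggregator_only_failure_is_excluded_with_cause(self, filter_config):
        profiles, molecules = self._profiles_and_mols(
            {"agg": CLOTRIMAZOLE, "clean": "NC(=O)c1ccccc1"}
        )
        passing, reports, _ = apply_filter_cascade(profiles, molecules, filter_config)
        assert set(passing) == {"clean"}
        assert reports["agg"].aggregator_flag
        assert "aggregator" in reports["agg"].causes

    def test_clean_report_means_included(self, filter_config):
        profiles, molecules = self._profiles_and_mols({"ok": "c1ccccc1CCO"})
        passing, reports, _ = apply_filter_cascade(profiles, molecules, filter_config)
        assert set(passing) == {"ok"} and reports["ok"].passes_all

    def test_missing_structure_is_logged_exclusion(self, filter_config):
        profiles, molecules = self._profiles_and_mols({"ok": "c1ccccc1CCO"})
        targets = frozenset(f"T{i}" for i in range(100))
        profiles["ghost"] = ActivityProfile("ghost", targets, frozenset())
        passing, reports, counts = apply_filter_cascade(
            profiles, molecules, filter_config
        )
        assert "ghost" not in passing
        assert reports["ghost"].causes  # no silent exclusions
        assert counts["missing_structure"] == 1

    def test_every_excluded_compound_has_a_recorded_cause(
        self, small_dataset, filter_config
    ):
        from promiscope.ingest import aggregate_profiles

        profiles = aggregate_profiles(small_dataset.records)
        passing, reports, _ = apply_filter_cascade(
            profiles, small_dataset.molecules, filter_config
        )
        for cid in set(profiles) - set(passing):
            assert reports[cid].causes

    def test_family_order_never_changes_final_passing_set(
        self, small_dataset, filter_config
    ):
        """The cascade is a pure set intersection of three family verdicts."""
        from promiscope.ingest import aggregate_profiles

        profiles = aggregate_profiles(small_dataset.records)
        molecules = small_dataset.molecules
        passing, reports, _ = apply_filter_cascade(profiles, molecules, filter_config)

        def family_pass(cid, family):
            r = reports[cid]
            return {
                "pains": not r.pains_flagged,
                "aggregator": not r.aggregator_flag,
                "medchem": not r.medchem_violations,
            }[family]

        for order in itertools.permutations(["pains", "aggregator", "medchem"]):
            surviving = set(profiles)
            for family in order:
                surviving = {c for c in surviving if family_pass(c, family)}
            assert surviving == set(passing)

    def test_adding_rules_only_shrinks_the_passing_set(self, small_dataset):
        from promiscope.ingest import aggregate_profiles

        profiles = aggregate_profiles(small_dataset.records)
        molecules = small_dataset.molecules
        base_rules = RuleSet.default()
        fewer = RuleSet(base_rules.rules[:5])
        cfg_few = FilterConfig(medchem_rules=fewer)
        cfg_all = FilterConfig(medchem_rules=base_rules)
        passing_few, _, _ = apply_filter_cascade(profiles, molecules, cfg_few)
        passing_all, _, _ = apply_filter_cascade(profiles, molecules, cfg_all)
        assert set(passing_all) <= set(passing_few)
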