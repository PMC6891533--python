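"""Single-cut fragmentation, MMP search and promiscuity-cliff detection."""

import pytest

from helpers import brute_force_mmps, mmp_signature
from promiscope.ingest import ActivityProfile, standardize_molecule
from promiscope.mmp import (
    H_SUBSTITUENT,
    SizeRestrictions,
    detect_promiscuity_cliffs,
    enumerate_single_cuts,
    find_mmps,
    reassemble,
)
from promiscope.synthetic import (
    RING_TEMPLATES,
    SUBSTITUENTS,
    _ANILIDE_PREFIX,
    worked_example,
)


def mol(smiles, cid="m"):
    return standardize_molecule(smiles, cid)


def series_molecules(n_scaffolds=3, n_subs=6):
    out = {}
    idx = 0
    for s in range(n_scaffolds):
        _, ring = RING_TEMPLATES[s]
        for k in range(n_subs):
            cid = f"m{idx:03d}"
            out[cid] = mol(_ANILIDE_PREFIX + ring.format(x=SUBSTITUENTS[k]), cid)
            idx += 1
    return out


class TestEnumerateSingleCuts:
    def test_benzene_has_no_eligible_bond(self):
        assert enumerate_single_cuts(mol("c1ccccc1")) == []

    def test_single_heavy_atom_has_no_cut(self):
        assert enumerate_single_cuts(mol("C")) == []

    def test_ethylbenzene_cuts_at_both_acyclic_bonds(self):
        frags = enumerate_single_cuts(mol("CCc1ccccc1"))
        subs = {f.substituent for f in frags}
        assert subs == {"*C", "*CC"}
        for f in frags:
            assert f.core_size + f.substituent_size == 8

    def test_hydrogen_cuts_offer_the_whole_molecule_as_core(self):
        frags = enumerate_single_cuts(mol("Cc1ccccc1"), include_hydrogen=True)
        h_frags = [f for f in frags if f.substituent == H_SUBSTITUENT]
        assert h_frags and all(f.substituent_size == 0 for f in h_frags)
        assert all(f.core_size == 7 for f in h_frags)

    def test_restrictions_drop_oversized_substituent_orientations(self):
        r = SizeRestrictions(max_substituent_heavy_atoms=1,
                             min_core_to_substituent_ratio=2.0,
                             max_transformation_difference_heavy_atoms=8)
        frags = enumerate_single_cuts(mol("CCc1ccccc1"), restrictions=r)
        assert {f.substituent for f in frags} == {"*C"}

    def test_reconstruction_roundtrip(self):
        molecule = mol("CCOc1ccc(Cl)cc1")
        for f in enumerate_single_cuts(molecule, include_hydrogen=True):
            assert reassemble(f.core, f.substituent) == molecule.smiles


class TestFindMMPs:
    def test_single_chlorine_substitution_is_an_mmp(self):
        mols = {
            "a": mol("O=C(Nc1ccccc1)c1ccccc1", "a"),
            "b": mol("O=C(Nc1ccccc1)c1ccc(Cl)cc1", "b"),
        }
        mmps = find_mmps(mols)
        assert len(mmps) == 1
        assert {mmps[0].substituent_a, mmps[0].substituent_b} == {
            H_SUBSTITUENT,
            "*Cl",
        }

    def test_two_independent_site_changes_are_not_an_mmp(self):
        mols = {
            "a": mol("O=C(Nc1ccccc1)c1ccccc1", "a"),
            "b": mol("O=C(Nc1ccc(F)cc1)c1ccc(Cl)cc1", "b"),
        }
        assert find_mmps(mols) == []

    def test_identical_molecules_form_no_pair(self):
        mols = {
            "a": mol("O=C(Nc1ccccc1)c1ccccc1", "a"),
            "b": mol("O=C(Nc1ccccc1)c1ccccc1", "b"),
        }
        assert find_mmps(mols) == []

    def test_duplicate_compound_ids_rejected(self):
        m = mol("CCO", "a")
        with pytest.raises(ValueError):
            find_mmps([m, m])

    def test_transformation_difference_restriction_is_enforced(self):
        r = SizeRestrictions(max_transformation_difference_heavy_atoms=1)
        mols = {
            "a": mol("O=C(Nc1ccccc1)c1ccccc1", "a"),          # H variant
            "b": mol("O=C(Nc1ccccc1)c1ccc(CCC)cc1", "b"),     # 3-atom substituent
            "c": mol("O=C(Nc1ccccc1)c1ccc(C)cc1", "c"),       # 1-atom substituent
        }
        pairs = {m.pair_key for m in find_mmps(mols, r)}
        assert ("a", "c") in pairs       # H vs CH3: difference 1
        assert ("a", "b") not in pairs   # H vs propyl: difference 3

    def test_result_is_independent_of_input_order(self):
        mols = series_molecules(2, 5)
        forward = find_mmps(dict(sorted(mols.items())))
        backward = find_mmps(dict(sorted(mols.items(), reverse=True)))
        assert mmp_signature(forward) == mmp_signature(backward)

    def test_every_pair_reconstructs_both_members(self):
        mols = series_molecules(2, 4)
        for m in find_mmps(mols):
            assert reassemble(m.core, m.substituent_a) == mols[m.compound_a].smiles
            assert reassemble(m.core, m.substituent_b) == mols[m.compound_b].smiles

    def test_matches_brute_force_oracle_on_mixed_set(self):
        mols = series_molecules(3, 6)
        # add structurally unrelated molecules to exercise non-matching cores
        for i, smi in enumerate(["CCO", "c1ccncc1", "CC(=O)Nc1ccccc1"]):
            mols[f"x{i}"] = mol(smi, f"x{i}")
        assert mmp_signature(find_mmps(mols)) == mmp_signature(
            brute_force_mmps(mols)
        )

    def test_planted_analog_series_fully_recovered_without_cross_pairs(self):
        mols = series_molecules(4, 6)
        series = {cid: int(cid[1:]) // 6 for cid in mols}
        mmps = find_mmps(mols)
        found = {m.pair_key for m in mmps}
        expected = {
            (a, b)
            for a in mols
            for b in mols
            if a < b and series[a] == series[b]
        }
        assert found == expected


class TestDetectCliffs:
    def test_worked_example_yields_exactly_one_cliff(self):
        molecules, profiles = worked_example()
        mmps = find_mmps(molecules)
        cliffs = detect_promiscuity_cliffs(mmps, profiles)
        assert len(cliffs) == 1
        c = cliffs[0]
        assert (c.pd_promiscuous, c.pd_partner) == (34, 0)
        assert c.shared_tested == 170
        assert c.promiscuous_id == "WE_PROM"

    @pytest.mark.parametrize(
        "pd_hi_member,pd_lo_member,expected",
        [(34, 0, 1), (34, 1, 1), (34, 2, 0), (9, 0, 0)],
    )
    def test_pd_thresholds_are_boundaries(self, pd_hi_member, pd_lo_member, expected):
        molecules, _ = worked_example()
        t = [f"T{i:03d}" for i in range(200)]
        profiles = {
            "WE_PROM": ActivityProfile(
                "WE_PROM", frozenset(t), frozenset(t[:pd_hi_member])
            ),
            "WE_PART": ActivityProfile(
                "WE_PART", frozenset(t), frozenset(t[:pd_lo_member])
            ),
        }
        mmps = find_mmps(molecules)
        assert len(detect_promiscuity_cliffs(mmps, profiles)) == expected

    def test_missing_profile_skips_pair(self):
        molecules, profiles = worked_example()
        mmps = find_mmps(molecules)
        assert (
            detect_promiscuity_cliffs(mmps, {"WE_PROM": profiles["WE_PROM"]}) == []
        )
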