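"""Target-class assignment and multiclass-ligand identification."""

import pytest

from promiscope.ingest import ActivityProfile, TargetRecord
from promiscope.target_classes import (
    CLASS_LABELS,
    ClassScheme,
    assign_class,
    class_count_histogram,
    class_profile,
    class_table,
    single_class_promiscuous,
)


@pytest.fixture(scope="module")
def scheme():
    return ClassScheme.default()


def make_targets(labels_by_tid):
    """Targets whose names carry keywords resolving to the wanted class."""
    name_for = {
        "Enzymes": ("tyrosine kinase", ""),
        "G protein-coupled receptors": ("receptor X", "G protein-coupled receptor"),
        "Ion channels": ("potassium channel", ""),
        "Receptors": ("interleukin receptor", ""),
        "Transporters": ("", "solute carrier family"),
        "Transcription factors": ("transcription factor Y", ""),
        "Unclassified": ("mystery protein", ""),
    }
    out = {}
    for tid, label in labels_by_tid.items():
        if label == "Others":
            out[tid] = TargetRecord(tid, "some protein", "", "Others")
        else:
            pname, fname = name_for[label]
            out[tid] = TargetRecord(tid, pname, fname)
    return out


class TestAssignClass:
    def test_gpcr_family_keyword(self, scheme):
        t = TargetRecord("T1", "5-HT receptor", "G protein-coupled receptor 1 family")
        assert assign_class(t, scheme) == "G protein-coupled receptors"

    def test_kinase_maps_to_enzymes(self, scheme):
        t = TargetRecord("T1", "mitogen-activated protein kinase 1", "")
        assert assign_class(t, scheme) == "Enzymes"

    def test_unmatched_name_falls_back_to_unclassified(self, scheme):
        t = TargetRecord("T1", "totally obscure polypeptide", "")
        assert assign_class(t, scheme) == "Unclassified"

    def test_specific_rules_beat_generic_receptor_fallback(self, scheme):
        gpcr = TargetRecord("T1", "adenosine receptor", "G protein-coupled receptor")
        nr = TargetRecord("T2", "nuclear receptor subfamily 3", "")
        plain = TargetRecord("T3", "ionotropic glutamate receptor subunit", "")
        assert assign_class(gpcr, scheme) == "G protein-coupled receptors"
        assert assign_class(nr, scheme) == "Transcription factors"
        assert assign_class(plain, scheme) == "Receptors"

    def test_others_only_via_explicit_label(self, scheme):
        explicit = TargetRecord("T1", "kinase anchor", "", "Others")
        assert assign_class(explicit, scheme) == "Others"

    def test_every_target_gets_exactly_one_class_and_table_sums(
        self, scheme, small_dataset
    ):
        table = class_table(small_dataset.targets, scheme)
        assert set(table) == set(CLASS_LABELS)
        assert sum(table.values()) == len(small_dataset.targets)

    def test_planted_classes_are_recovered(self, scheme, small_dataset):
        for tid, target in small_dataset.targets.items():
            assert assign_class(target, scheme) == small_dataset.target_classes[tid]


def make_class_profile(scheme, pd_value, active_labels, n_extra_tested=120):
    """Build an ActivityProfile whose actives map to the given labels."""
    labels = list(active_labels)
    plan = {}
    tids_active = []
    for i in range(pd_value):
        tid = f"A{i:03d}"
        plan[tid] = labels[i % len(labels)]
        tids_active.append(tid)
    for i in range(n_extra_tested):
        plan[f"B{i:03d}"] = "Enzymes" if i % 2 else "Ion channels"
    targets = make_targets(plan)
    profile = ActivityProfile(
        "cpd",
        frozenset(plan),
        frozenset(tids_active),
    )
    return class_profile(profile, targets, scheme)


class TestClassProfile:
    def test_pd12_across_two_classes_is_multiclass(self, scheme):
        cp = make_class_profile(scheme, 12, ["Enzymes", "Ion channels"])
        assert cp.is_multiclass

    def test_pd12_single_class_is_not_multiclass(self, scheme):
        cp = make_class_profile(scheme, 12, ["Enzymes"])
        assert not cp.is_multiclass
        assert cp.active_classes == {"Enzymes"}

    def test_pd9_across_three_classes_misses_pd_threshold(self, scheme):
        cp = make_class_profile(
            scheme, 9, ["Enzymes", "Ion channels", "Transporters"]
        )
        assert not cp.is_multiclass

    def test_unknown_target_id_is_a_hard_error_listing_ids(self, scheme):
        profile = ActivityProfile("c", frozenset({"TX"}), frozenset())
        with pytest.raises(KeyError, match="TX"):
            class_profile(profile, {}, scheme)


class TestDerivedSets:
    def test_histogram_counts_by_brute_force(self, scheme):
        cps = [
            make_class_profile(scheme, 11, ["Enzymes"]),
            make_class_profile(
                scheme, 12, ["Enzymes", "Receptors", "Ion channels", "Transporters"]
            ),
            make_class_profile(
                scheme,
                16,
                ["Enzymes", "Receptors", "Ion channels", "Transporters"],
            ),
        ]
        assert class_count_histogram(cps) == {1: 1, 4: 2}

    def test_histogram_empty_input(self):
        assert class_count_histogram([]) == {}

    def test_histogram_total_conservation(self, scheme, small_dataset):
        from promiscope.ingest import aggregate_profiles

        profiles = aggregate_profiles(small_dataset.records)
        cps = [
            class_profile(p, small_dataset.targets, scheme)
            for p in profiles.values()
        ]
        hist = class_count_histogram(cps)
        n_hi = sum(1 for cp in cps if cp.pd >= 10)
        assert sum(hist.values()) == n_hi

    def test_single_class_promiscuous_membership(self, scheme):
        included = make_class_profile(scheme, 3, ["Enzymes"])
        low_pd = make_class_profile(scheme, 1, ["Enzymes"])
        spread = make_class_profile(scheme, 3, ["Enzymes", "Ion channels"])
        assert single_class_promiscuous([included]) == {"cpd"}
        assert single_class_promiscuous([low_pd]) == set()
        assert single_class_promiscuous([spread]) == set()

    def test_multiclass_and_single_class_partition_the_promiscuous(
        self, scheme, small_dataset
    ):
        from promiscope.ingest import aggregate_profiles

        profiles = aggregate_profiles(small_dataset.records)
        cps = [
            class_profile(p, small_dataset.targets, scheme)
            for p in profiles.values()
        ]
        hi = {cp.compound_id for cp in cps if cp.pd >= 10}
        multi = {cp.compound_id for cp in cps if cp.is_multiclass}
        single_hi = {
            cp.compound_id
            for cp in cps
            if cp.pd >= 10 and len(cp.active_classes) == 1
        }
        assert multi | single_hi == hi
        assert not multi & single_hi
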