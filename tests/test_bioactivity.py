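"""Activity trust filters and binder / non-binder pair classification."""

from collections import defaultdict

import pytest
from hypothesis import given, settings, strategies as st

from pharmpred import (
    ActivityRecord,
    BindingLabel,
    CurationThresholds,
    build_target_datasets,
    classify_pair,
    filter_activities,
)


def rec(value=500.0, relation="=", organism="Homo sapiens", assay="B", conf=8,
        atype="IC50", unit="nM", comment=None, cid="C1", target="T1", smiles="CCO"):
    return ActivityRecord(
        compound_id=cid, smiles=smiles, target_id=target, organism=organism,
        assay_type=assay, confidence=conf, activity_type=atype, relation=relation,
        value=value, unit=unit, validity_comment=comment,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "record, why",
        [
            (rec(organism="Rattus norvegicus"), "organism"),
            (rec(assay="A"), "assay_type"),
            (rec(conf=6), "confidence"),
            (rec(atype="AC50"), "activity_type"),
            (rec(unit="uM"), "unit"),
            (rec(value=0.0), "zero_value"),
            (rec(comment="Outside typical range"), "validity_comment"),
        ],
    )
    def test_each_predicate_drops_and_logs(self, record, why):
        log = []
        kept = filter_activities([record], drop_log=log)
        assert kept == []
        assert log == [(record, why)]

    @pytest.mark.parametrize(
        "record",
        [rec(), rec(assay="F"), rec(conf=7), rec(atype="Potency"), rec(unit="nm"),
         rec(atype="Kd"), rec(atype="EC50"), rec(atype="Ki")],
    )
    def test_trusted_records_pass(self, record):
        assert filter_activities([record]) == [record]

    def test_every_drop_logged_exactly_once(self, assay_fixture):
        activities, _ = assay_fixture
        log = []
        kept = filter_activities(activities, drop_log=log)
        assert len(kept) + len(log) == len(activities)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "records, label",
        [
            ([rec(500, "=")], BindingLabel.STRONG),
            ([rec(1000, "=")], BindingLabel.STRONG),      # inclusive bound
            ([rec(800, "<")], BindingLabel.STRONG),
            ([rec(800, "<=")], BindingLabel.STRONG),      # <= counts as <
            ([rec(50000, ">")], BindingLabel.NON),
            ([rec(30000, "=")], BindingLabel.NON),        # inclusive bound
            ([rec(50000, ">=")], BindingLabel.NON),
            ([rec(500, "="), rec(40000, "=")], BindingLabel.CONFLICT),
            ([rec(5000, "=")], BindingLabel.INDETERMINATE),
            ([rec(1001, "=")], BindingLabel.INDETERMINATE),
            ([rec(29999, "=")], BindingLabel.INDETERMINATE),
        ],
    )
    def test_threshold_and_relation_semantics(self, records, label):
        assert classify_pair(records) is label

    @pytest.mark.parametrize(
        "records",
        [
            [rec(50000, "<")],   # '<' on a high value says nothing about non-binding
            [rec(500, ">")],     # '>' on a low value says nothing about binding
            [rec(500, "~")],     # '~' qualifies nothing
            [rec(50000, "~")],
        ],
    )
    def test_directional_relations_never_misqualify(self, records):
        assert classify_pair(records) is BindingLabel.INDETERMINATE

    def test_empty_pair_is_a_precondition_violation(self):
        with pytest.raises(ValueError):
            classify_pair([])

    def test_fixture_labels_reproduced(self, assay_fixture):
        activities, expected = assay_fixture
        trusted = filter_activities(activities)
        pairs = defaultdict(list)
        for r in trusted:
            pairs[(r.target_id, r.compound_id)].append(r)
        assert set(pairs) == set(expected)
        for key, recs in pairs.items():
            assert classify_pair(recs) is expected[key], key


class TestTargetDatasets:
    def test_disjointness_and_eligibility(self, target_datasets):
        datasets, summary = target_datasets
        for d in datasets:
            assert d.binder_smiles().isdisjoint(
                {s.canonical_smiles for s in d.nonbinders}
            )
        by_id = {d.target_id: d for d in datasets}
        assert by_id["T_SEP"].eligible
        assert not by_id["T_SMALL"].eligible
        assert summary.n_eligible_targets == 1

    def test_exactly_20_20_is_eligible(self):
        activities = []
        for i in range(20):
            activities.append(rec(cid=f"B{i}", smiles="c1ccccc1" + "C" * (i + 1), value=100))
            activities.append(rec(cid=f"N{i}", smiles="C1CCCCC1" + "C" * (i + 1), value=50000))
        datasets, _ = build_target_datasets(activities)
        assert datasets[0].eligible

    def test_19_binders_is_not_eligible(self):
        activities = []
        for i in range(19):
            activities.append(rec(cid=f"B{i}", smiles="c1ccccc1" + "C" * (i + 1), value=100))
        for i in range(25):
            activities.append(rec(cid=f"N{i}", smiles="C1CCCCC1" + "C" * (i + 1), value=50000))
        datasets, _ = build_target_datasets(activities)
        assert not datasets[0].eligible

    def test_conflict_pairs_enter_neither_set(self):
        activities = [rec(value=100), rec(value=50000)]
        datasets, _ = build_target_datasets(activities)
        d = datasets[0]
        assert not d.binders and not d.nonbinders


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=1, max_value=1e6, allow_nan=False),
            st.sampled_from(["=", "<", ">", "<=", ">=", "~"]),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_label_is_exhaustive_and_conflict_exclusion_gives_disjoint_sets(pair_data):
    records = [rec(value=v, relation=r) for v, r in pair_data]
    label = classify_pair(records)
    assert label in BindingLabel
    datasets, _ = build_target_datasets(records)
    d = datasets[0]
    assert d.binder_smiles().isdisjoint({s.canonical_smiles for s in d.nonbinders})
    in_binders = len(d.binders) == 1
    assert in_binders == (label is BindingLabel.STRONG)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=1, max_value=1e5, allow_nan=False),
            st.sampled_from(["=", "<", ">"]),
        ),
        min_size=1,
        max_size=6,
    ),
    st.floats(min_value=1000, max_value=20000),
)
def test_raising_strong_threshold_never_shrinks_binder_sets(pair_data, new_max):
    records = [rec(value=v, relation=r) for v, r in pair_data]
    base = CurationThresholds()
    raised = CurationThresholds(strong_max_nm=max(new_max, base.strong_max_nm))
    ds_base, _ = build_target_datasets(records, base)
    ds_raised, _ = build_target_datasets(records, raised)
    assert ds_base[0].binder_smiles() <= ds_raised[0].binder_smiles()
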