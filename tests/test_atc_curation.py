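"""ATC code parsing and the curation cascade."""

import pytest
from hypothesis import given, settings, strategies as st

from pharmpred import ambiguity_key, canonicalize, curate, parse_atc
from pharmpred.atc import (
    ATCRecord,
    ATCValidationError,
    EmptyDatasetError,
)


@pytest.mark.parametrize(
    "code, level1, level4",
    [("J01MA24", "J", "J01MA"), ("D10AF05", "D", "D10AF"), ("A02BC01", "A", "A02BC")],
)
def test_parse_atc_levels(code, level1, level4):
    atc = parse_atc(code)
    assert atc.level1 == level1
    assert atc.level4 == level4
    assert atc.level5 == code
    # every level is a prefix of the next
    assert code.startswith(atc.level4)
    assert atc.level4.startswith(atc.level3)
    assert atc.level3.startswith(atc.level2)
    assert atc.level2.startswith(atc.level1)


@pytest.mark.parametrize("bad", ["J01M", "j01ma24", "J01MA2", "1234567", "J01MA240"])
def test_parse_atc_rejects_malformed_codes(bad):
    with pytest.raises(ATCValidationError):
        parse_atc(bad)


def test_ambiguity_key_identity_and_stereo():
    assert ambiguity_key(canonicalize("CCO")) == ambiguity_key(canonicalize("OCC"))
    assert ambiguity_key(canonicalize("CCO")) != ambiguity_key(canonicalize("CCN"))
    # stereoisomers stay distinct: an enantiomer pair must not trigger
    # mutual ambiguity removal
    assert ambiguity_key(canonicalize("C[C@H](N)C(=O)O")) != ambiguity_key(
        canonicalize("C[C@@H](N)C(=O)O")
    )


def _rec(code, name="x", smiles="CCO", combo=False):
    return ATCRecord(parse_atc(code), name, smiles, combo)


BASE = [
    _rec("A01AA01", smiles="c1ccccc1CC"),
    _rec("A01AA02", smiles="c1ccccc1CCC"),
]


class TestCurationRules:
    def test_v_codes_removed(self):
        ds, log = curate(BASE + [_rec("V03AB01", smiles="CCCO")])
        assert log.counts["v_code"] == 1
        assert all(not label.startswith("V") for label in ds.labels)

    def test_combinations_removed_by_flag_and_by_name(self):
        extra = [
            _rec("A01AA03", name="drug A and drug B", smiles="CCCN"),
            _rec("A01AA04", name="plain", smiles="CCCS", combo=True),
        ]
        _, log = curate(BASE + extra)
        assert log.counts["combination"] == 2

    def test_ambiguous_structure_loses_all_codes(self):
        extra = [
            _rec("A01AA03", smiles="OCCCCO"),
            _rec("B01AB02", smiles="OCCCCO"),
        ]
        ds, log = curate(BASE + extra)
        assert log.counts["ambiguous"] == 2
        assert "OCCCCO" not in {s.canonical_smiles for s in ds.structures}

    def test_same_code_duplicates_do_not_count_as_ambiguity(self):
        extra = [
            _rec("A01AA03", smiles="CCCCO"),
            _rec("A01AA03", smiles="OCCCC"),  # same molecule, same code
        ]
        _, log = curate(BASE + extra)
        assert log.counts["ambiguous"] == 0
        assert log.counts["duplicate"] == 1

    def test_structureless_and_salt_records_removed(self):
        extra = [
            _rec("A01AA03", smiles=None),
            _rec("A01AA04", smiles="C(("),
            _rec("A01AA05", smiles="[Na+].CC(=O)[O-]"),
        ]
        _, log = curate(BASE + extra)
        assert log.counts["no_structure"] == 2
        assert log.counts["salt"] == 1

    def test_x_group_removed_entirely(self):
        extra = [_rec("J01MX01", smiles="SCCO"), _rec("J01MX02", smiles="SCCN")]
        ds, log = curate(BASE + extra)
        assert log.counts["x_group"] == 2
        assert not any(label.endswith("X") for label in ds.labels)

    def test_salt_removal_can_create_a_singleton(self):
        # record-level rules run before group pruning: the salt goes first,
        # leaving its partner alone in the group, which is then pruned too
        extra = [
            _rec("G03CA01", smiles="OCC1CCCCC1O"),
            _rec("G03CA02", smiles="[K+].OC(=O)C1CCCCC1"),
        ]
        ds, log = curate(BASE + extra)
        assert log.counts["salt"] == 1
        assert log.counts["singleton_group"] == 1
        assert "G03CA" not in ds.groups

    def test_empty_result_raises(self):
        with pytest.raises(EmptyDatasetError):
            curate([_rec("V03AB01")])


def test_toyset_audit_matches_planted_ground_truth(atc_toyset):
    records, expected = atc_toyset
    ds, log = curate(records)
    for rule, n in expected.items():
        assert log.counts[rule] == n, rule
    assert log.check_conservation()
    # structural invariants of the output
    assert all(len(members) >= 2 for members in ds.groups.values())
    assert not any(label.startswith("V") or label.endswith("X") for label in ds.groups)


def test_curation_is_idempotent(atc_toyset):
    records, _ = atc_toyset
    ds, _ = curate(records)
    # re-number codes uniquely within each label so rewrapping itself does
    # not create artificial duplicates
    seen = {}
    rewrapped = []
    for s, label in ds.records:
        k = seen.get(label, 0) + 1
        seen[label] = k
        rewrapped.append(ATCRecord(parse_atc(f"{label}{k:02d}"), s.id, s.canonical_smiles))
    ds2, log2 = curate(rewrapped)
    assert log2.n_removed == 0
    assert len(ds2.records) == len(ds.records)


# a small pool of valid, structurally distinct molecules for random fixtures
_POOL_SMILES = ["CCO", "CCN", "CCS", "CCCO", "CCCN", "c1ccccc1C", "C1CCCCC1O",
                None, "[Na+].CC(=O)[O-]", "bad(("]
_POOL_CODES = ["A01AA01", "A01AA02", "B01AB01", "B01AB02", "V03AB01",
               "J01MX01", "C07AB03"]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(_POOL_CODES),
            st.sampled_from(_POOL_SMILES),
            st.booleans(),
        ),
        min_size=1,
        max_size=15,
    )
)
def test_conservation_holds_on_random_inputs(raw):
    records = [
        ATCRecord(parse_atc(code), f"name-{i}{' and b' if combo else ''}", smi)
        for i, (code, smi, combo) in enumerate(raw)
    ]
    try:
        _, log = curate(records)
    except EmptyDatasetError:
        return
    assert log.check_conservation()
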