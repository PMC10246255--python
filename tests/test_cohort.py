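"""Data-preparation rules: grouping, lab filters, index dates, labels, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrisk.cohort import (
    CodeSets,
    CohortSample,
    LabelDecision,
    assign_label,
    build_cohort,
    build_sequence,
    build_vocabulary,
    filter_labs,
    group_code,
    select_index_date,
    split_dataset,
)


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "channel", "code", "flag"])
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# code grouping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "code,expected",
    [("F43.10", "F43"), ("F10.20", "F10"), ("E11", "E11"), ("309.81", "309"),
     ("f43·11", "F43")],
)
def test_group_code(code, expected):
    assert group_code(code) == expected


def test_group_code_short_code_warns():
    with pytest.warns(UserWarning):
        assert group_code("V2") == "V2"


@given(st.text(alphabet="ABCdef0123456789.·", min_size=3, max_size=10))
@settings(max_examples=50, deadline=None)
def test_group_code_is_idempotent_prefix(code):
    g = group_code(code)
    assert len(g) <= 3
    assert g == g.upper()


# ---------------------------------------------------------------------------
# lab filter
# ---------------------------------------------------------------------------

def test_filter_labs_flag_and_frequency_rules():
    rows = []
    # 99 abnormal occurrences of LAB_A -> dropped at threshold 100
    rows += [("P1", "2010-01-01", "lab", "LAB_A", "HIGH")] * 99
    # 100 abnormal occurrences of LAB_B -> retained (boundary inclusive)
    rows += [("P1", "2010-01-01", "lab", "LAB_B", "ABNORMAL")] * 100
    # NORMAL labs never retained, and do not count toward frequency
    rows += [("P1", "2010-01-01", "lab", "LAB_A", "NORMAL")] * 50
    rows += [("P1", "2010-01-02", "diagnosis", "E11.9", "")]
    out = filter_labs(_events(rows), min_frequency=100)
    assert (out.loc[out["channel"] == "lab", "code"] == "LAB_B").all()
    assert (out["channel"] == "lab").sum() == 100
    assert (out["channel"] == "diagnosis").sum() == 1  # non-labs pass through


# ---------------------------------------------------------------------------
# index date and labels
# ---------------------------------------------------------------------------

@pytest.fixture()
def simple_code_sets():
    return CodeSets(ptsd_codes=frozenset({"F43.10"}), asud_codes=frozenset({"F10.20"}))


def test_select_index_date_latest_eligible(simple_code_sets):
    ev = _events([
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
        ("P1", "2010-03-01", "diagnosis", "E11.9", ""),
        ("P1", "2010-06-01", "diagnosis", "E11.9", ""),
        ("P1", "2010-07-15", "diagnosis", "F10.20", ""),
    ])
    assert select_index_date(ev, simple_code_sets) == pd.Timestamp("2010-06-01")


def test_select_index_date_none_without_later_encounter(simple_code_sets):
    ev = _events([("P1", "2010-01-01", "diagnosis", "F43.10", "")])
    assert select_index_date(ev, simple_code_sets) is None
    ev2 = _events([
        ("P1", "2009-12-01", "diagnosis", "E11.9", ""),
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
    ])
    assert select_index_date(ev2, simple_code_sets) is None


def test_select_index_date_requires_ptsd(simple_code_sets):
    ev = _events([("P1", "2010-01-01", "diagnosis", "E11.9", "")])
    with pytest.raises(ValueError):
        select_index_date(ev, simple_code_sets)


@pytest.mark.parametrize(
    "asud_date,expected",
    [("2010-07-15", LabelDecision("case", "asud_within_window")),       # 44 d
     ("2010-08-30", LabelDecision("case", "asud_within_window")),       # day 90
     ("2010-11-01", LabelDecision("control", "asud_after_window"))],    # 153 d
)
def test_assign_label_window_boundary(simple_code_sets, asud_date, expected):
    ev = _events([
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
        ("P1", "2010-06-01", "diagnosis", "E11.9", ""),
        ("P1", asud_date, "diagnosis", "F10.20", ""),
    ])
    got = assign_label(ev, pd.Timestamp("2010-06-01"), simple_code_sets)
    assert got == expected


def test_assign_label_exclusions(simple_code_sets):
    same_day = _events([
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
        ("P1", "2010-01-01", "diagnosis", "F10.20", ""),
    ])
    got = assign_label(same_day, pd.Timestamp("2010-02-01"), simple_code_sets)
    assert got.label == "excluded" and got.reason == "asud_same_day_as_ptsd"

    before = _events([
        ("P1", "2009-06-01", "diagnosis", "F10.20", ""),
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
    ])
    got = assign_label(before, pd.Timestamp("2010-02-01"), simple_code_sets)
    assert got.label == "excluded" and got.reason == "asud_before_ptsd"


def test_assign_label_no_asud_is_control(simple_code_sets):
    ev = _events([
        ("P1", "2010-01-01", "diagnosis", "F43.10", ""),
        ("P1", "2010-05-01", "diagnosis", "E11.9", ""),
    ])
    got = assign_label(ev, pd.Timestamp("2010-05-01"), simple_code_sets)
    assert got == LabelDecision("control", "no_asud_record")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def test_build_sequence_gaps_and_window():
    ev = _events([
        ("P1", "2010-05-02", "diagnosis", "E11", ""),     # index - 30
        ("P1", "2010-06-01", "diagnosis", "E11", ""),     # index day
        ("P1", "2009-05-31", "diagnosis", "OLD", ""),     # index - 366: out
    ])
    visits, gaps = build_sequence(ev, pd.Timestamp("2010-06-01"))
    assert [d.strftime("%Y-%m-%d") for d, _ in visits] == ["2010-05-02", "2010-06-01"]
    assert gaps == [0, 30]
    assert all("OLD" not in toks for _, toks in visits)


def test_build_sequence_boundary_inclusive_at_lookback_start():
    ev = _events([("P1", "2009-06-01", "diagnosis", "E11", "")])  # exactly index-365
    visits, _ = build_sequence(ev, pd.Timestamp("2010-06-01"))
    assert len(visits) == 1


def test_build_sequence_preserves_duplicates_and_appends_sdoh():
    ev = _events([
        ("P1", "2010-06-01", "lab", "LAB1", "HIGH"),
        ("P1", "2010-06-01", "lab", "LAB1", "HIGH"),
    ])
    visits, gaps = build_sequence(ev, pd.Timestamp("2010-06-01"),
                                  sdoh_tokens=("SEX:F",))
    (date, tokens), = visits
    assert tokens.count("LAB1") == 2
    assert "SEX:F" in tokens
    assert gaps == [0]


# ---------------------------------------------------------------------------
# vocabulary and splits
# ---------------------------------------------------------------------------

def _sample(pid, tokens):
    return CohortSample(
        patient_id=pid, index_date=pd.Timestamp("2010-06-01"), label="control",
        visits=[(pd.Timestamp("2010-06-01"), tuple(tokens))], gap_days=[0],
    )


def test_build_vocabulary_ranking_and_cap():
    samples = [_sample("P1", ["A", "A", "B", "C"]), _sample("P2", ["A", "B", "D"])]
    vocab = build_vocabulary(samples, max_size=30_000)
    assert vocab.token_to_id["A"] == 1  # most frequent
    assert set(vocab.token_to_id) == {"A", "B", "C", "D"}
    capped = build_vocabulary(samples, max_size=3)
    assert set(capped.token_to_id) == {"A", "B"}
    assert capped.size == 3


def test_build_vocabulary_tie_breaks_lexicographically():
    samples = [_sample("P1", ["Z", "A"])]
    vocab = build_vocabulary(samples, max_size=2)
    assert set(vocab.token_to_id) == {"A"}


def test_split_sizes_disjoint_exhaustive_and_seeded():
    samples = [_sample(f"P{i}", ["A"]) for i in range(100)]
    tr, va, te = split_dataset(samples, seed=5)
    assert (len(tr), len(va), len(te)) == (80, 10, 10)
    ids = [s.patient_id for part in (tr, va, te) for s in part]
    assert sorted(ids) == sorted(s.patient_id for s in samples)
    tr2, va2, te2 = split_dataset(samples, seed=5)
    assert [s.patient_id for s in tr] == [s.patient_id for s in tr2]
    assert [s.patient_id for s in va] == [s.patient_id for s in va2]


# ---------------------------------------------------------------------------
# end-to-end build
# ---------------------------------------------------------------------------

def test_cohort_categories_disjoint_and_exhaustive(tiny_cohort, tiny_population):
    audit = tiny_cohort.audit
    n_ptsd_patients = tiny_population.config.n_patients
    assert len(audit) == n_ptsd_patients
    assert audit["patient_id"].is_unique
    labeled = set(audit.loc[audit["decision"].isin(["case", "control"]), "patient_id"])
    assert labeled == {s.patient_id for s in tiny_cohort.samples}


def test_cohort_sample_invariants(tiny_cohort):
    for s in tiny_cohort.samples:
        lo = s.index_date - pd.Timedelta(days=365)
        dates = [d for d, _ in s.visits]
        assert all(lo <= d <= s.index_date for d in dates)
        assert dates == sorted(dates)
        assert s.gap_days[0] == 0
        assert all(g >= 0 for g in s.gap_days)
        assert len(s.gap_days) == len(s.visits)


def test_cohort_rebuild_is_idempotent(tiny_population, code_sets):
    kw = dict(demographics=tiny_population.demographics,
              sdoh_table=tiny_population.sdoh_zip, min_lab_frequency=5)
    r1 = build_cohort(tiny_population.events, code_sets, **kw)
    r2 = build_cohort(tiny_population.events, code_sets, **kw)
    assert [s.patient_id for s in r1.samples] == [s.patient_id for s in r2.samples]
    for a, b in zip(r1.samples, r2.samples):
        assert a == b
    assert r1.vocabulary.token_to_id == r2.vocabulary.token_to_id


def test_cohort_labels_match_ground_truth_outcomes(tiny_cohort, tiny_population):
    """Patients labeled case must have a truth outcome date within 90 days
    of their index date."""
    truth = tiny_population.truth.outcome_date
    for s in tiny_cohort.samples:
        onset = truth[s.patient_id]
        if s.label == "case":
            assert onset is not None
            delta = (pd.Timestamp(onset) - s.index_date).days
            assert 0 < delta <= 90


def test_with_and_without_sdoh_differ_only_by_sdoh_tokens(tiny_population, code_sets):
    kw = dict(demographics=tiny_population.demographics,
              sdoh_table=tiny_population.sdoh_zip, min_lab_frequency=5)
    with_s = build_cohort(tiny_population.events, code_sets, include_sdoh=True, **kw)
    without = build_cohort(tiny_population.events, code_sets, include_sdoh=False, **kw)
    by_pid = {s.patient_id: s for s in without.samples}
    assert set(by_pid) == {s.patient_id for s in with_s.samples}
    for s in with_s.samples:
        plain = by_pid[s.patient_id]
        from collections import Counter

        diff = Counter(s.all_tokens()) - Counter(plain.all_tokens())
        assert set(diff) == set(s.sdoh_tokens)
        assert s.label == plain.label and s.index_date == plain.index_date
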