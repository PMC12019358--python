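"""Modality mapping, attrition filters, switch detection, demographics."""

import numpy as np
import pandas as pd
import pytest

from switchscope.cohort import (
    AttritionReport,
    TimelineEntry,
    apply_filters,
    demographic_comparison,
    detect_switches,
    map_to_modality,
)
from switchscope.patterns import EXCLUDED, UNMAPPED, Modality, load_default_table

TABLE = load_default_table()


@pytest.mark.parametrize(
    "name, expected",
    [
        ("norethindrone 0.35 mg oral tablet", Modality.ORAL),
        ("etonogestrel 68 mg subdermal implant", Modality.IMPLANT),
        ("levonorgestrel 52 mg intrauterine device (Mirena)", Modality.IUD),
        ("medroxyprogesterone acetate 150 mg/mL intramuscular injection", Modality.INJECTABLE),
        ("norelgestromin-ethinyl estradiol transdermal patch", Modality.TRANSDERMAL),
        ("etonogestrel-ethinyl estradiol vaginal ring (NuvaRing)", Modality.INTRAVAGINAL),
        ("levonorgestrel 1.5 mg tablet (emergency)", EXCLUDED),
        ("latex condom", EXCLUDED),
        ("vaginal pH modulator gel (Phexxi)", EXCLUDED),
        ("lisinopril 10 mg", UNMAPPED),
    ],
)
def test_drug_name_modality_mapping(name, expected):
    assert map_to_modality(name, table=TABLE) == expected


def test_empty_drug_name_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        TABLE.map("  ")


def _mini_tables():
    orders = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P1", "P1"],
            "encounter_date": [0, 0, 100, 200],
            "start_date": [0, 0, np.nan, 200],
            "drug_name": ["norethindrone oral tablet"] * 2 + ["NuvaRing vaginal ring"] * 2,
            "therapeutic_class": ["CONTRACEPTIVES"] * 4,
        }
    )
    long_text = " ".join(["word"] * 60)
    notes = pd.DataFrame(
        {
            "note_id": ["N1", "N2", "N3"],
            "patient_id": ["P1", "P1", "P1"],
            "encounter_date": [0, 200, 500],
            "text": [long_text, long_text, long_text],
        }
    )
    return orders, notes


def test_missing_start_date_and_duplicates_filtered():
    orders, notes = _mini_tables()
    filtered, report = apply_filters(orders, notes)
    removed = report.removed()
    assert removed["missing_start_date"] == 1
    assert removed["duplicate"] == 1  # two identical oral orders at day 0
    assert len(filtered) == 2
    assert set(filtered["note_id"]) == {"N1", "N2"}


def test_attrition_conservation(noisy_sim):
    _, report = apply_filters(noisy_sim.orders, noisy_sim.notes)
    rows = report.rows
    for (_, _, prev_remaining, _), (_, removed, remaining, _) in zip(rows, rows[1:]):
        assert remaining == prev_remaining - removed
    assert all(r >= 0 for _, r, _, _ in rows)
    # patients remaining never increases
    pats = [p for _, _, _, p in rows]
    assert pats == sorted(pats, reverse=True)


def test_attrition_report_rejects_inconsistent_rows():
    rep = AttritionReport()
    rep.add("initial", 0, 100, 10)
    with pytest.raises(ValueError, match="conservation"):
        rep.add("broken", 5, 90, 10)


def test_followup_anchor_switchable():
    orders, notes = _mini_tables()
    # with anchor=last: last order day 200, latest encounter 500 -> 300 days ok
    _, rep_last = apply_filters(orders, notes, followup_anchor="last")
    assert rep_last.removed()["no_followup"] == 0
    # shrink note horizon so only first-order anchor is satisfied
    notes_short = notes.copy()
    notes_short.loc[notes_short["note_id"] == "N3", "encounter_date"] = 250
    _, rep2 = apply_filters(orders, notes_short, followup_anchor="last")
    assert rep2.removed()["no_followup"] > 0
    _, rep3 = apply_filters(orders, notes_short, followup_anchor="first")
    assert rep3.removed()["no_followup"] == 0


def test_schema_violation_names_column():
    orders, notes = _mini_tables()
    with pytest.raises(ValueError, match="start_date"):
        apply_filters(orders.drop(columns=["start_date"]), notes)


def _tl(*modality_sets):
    return [
        TimelineEntry(start_date=i, encounter_date=i, modalities=frozenset(ms), note_id=f"N{i}")
        for i, ms in enumerate(modality_sets)
    ]


def test_identical_consecutive_sets_emit_nothing():
    assert detect_switches(_tl({Modality.ORAL}, {Modality.ORAL})) == []


def test_single_switch_sets():
    (ev,) = detect_switches(_tl({Modality.ORAL}, {Modality.INTRAVAGINAL}), "P1")
    assert ev.stopped == {Modality.ORAL}
    assert ev.started == {Modality.INTRAVAGINAL}
    assert ev.note_id == "N1"


def test_return_to_previous_modality_counts_twice():
    events = detect_switches(_tl({Modality.ORAL}, {Modality.IUD}, {Modality.ORAL}))
    assert len(events) == 2


def test_multi_modality_sets_use_set_difference():
    (ev,) = detect_switches(
        _tl({Modality.ORAL, Modality.TRANSDERMAL}, {Modality.ORAL, Modality.IUD})
    )
    assert ev.stopped == {Modality.TRANSDERMAL}
    assert ev.started == {Modality.IUD}


def test_unsorted_timeline_rejected():
    tl = _tl({Modality.ORAL}, {Modality.IUD})[::-1]
    with pytest.raises(ValueError, match="sorted"):
        detect_switches(tl)


def test_reversed_timeline_swaps_stopped_and_started():
    rng = np.random.default_rng(11)
    mods = list(Modality)
    for _ in range(50):
        sets = []
        for _ in range(rng.integers(2, 6)):
            k = int(rng.integers(1, 3))
            sets.append(frozenset(rng.choice(mods, size=k, replace=False)))
        fwd = detect_switches(_tl(*sets))
        rev = detect_switches(_tl(*sets[::-1]))
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev[::-1]):
            assert a.stopped == b.started and a.started == b.stopped


def test_identical_age_samples_give_t_zero_p_one():
    demo = pd.DataFrame(
        {"patient_id": ["a", "b", "c"], "age_first_rx": [20.0, 25.0, 30.0],
         "race_ethnicity": ["White", "Asian", "White"], "preferred_language": ["English"] * 3}
    )
    out = demographic_comparison(demo, demo.copy())
    assert out["age_first_rx"]["t_statistic"] == pytest.approx(0.0)
    assert out["age_first_rx"]["p_value"] == pytest.approx(1.0)


def test_homogeneous_counts_give_chi2_zero():
    a = pd.DataFrame(
        {"patient_id": range(20), "age_first_rx": 25.0,
         "race_ethnicity": ["White"] * 10 + ["Asian"] * 10, "preferred_language": ["English"] * 20}
    )
    out = demographic_comparison(a, a.copy())
    assert out["race_ethnicity"]["chi2"] == pytest.approx(0.0)
    assert out["preferred_language"]["test"] == "not applicable"


def test_chi2_matches_textbook_formula_on_2x3_table():
    counts_a = {"White": 10, "Asian": 20, "Other": 30}
    counts_b = {"White": 20, "Asian": 20, "Other": 20}
    a = pd.DataFrame(
        {"patient_id": range(60), "age_first_rx": 25.0, "preferred_language": "English",
         "race_ethnicity": [k for k, v in counts_a.items() for _ in range(v)]}
    )
    b = pd.DataFrame(
        {"patient_id": range(60, 120), "age_first_rx": 26.0, "preferred_language": "English",
         "race_ethnicity": [k for k, v in counts_b.items() for _ in range(v)]}
    )
    # independent brute-force expected-count computation
    obs = np.array([[10, 20, 30], [20, 20, 20]], float)
    expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
    chi2_oracle = float(((obs - expected) ** 2 / expected).sum())
    out = demographic_comparison(a, b)
    assert out["race_ethnicity"]["chi2"] == pytest.approx(chi2_oracle)


def test_empty_cohort_rejected():
    demo = pd.DataFrame({"patient_id": [], "age_first_rx": [], "race_ethnicity": [], "preferred_language": []})
    with pytest.raises(ValueError, match="non-empty"):
        demographic_comparison(demo, demo)
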