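"""Prevalent/incident derivation and subgroup contrasts, checked against
hand-computed tables and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from metsom.outcomes import (
    CARDIOMETABOLIC,
    DiseaseDefinition,
    binary_panel,
    default_definitions,
    derive_disease_status,
    expand_code_range,
    incidence_hazard_ratios,
    incidence_rates,
    load_definitions,
    prevalence_odds_ratios,
    save_definitions,
)


def _participants(rows):
    df = pd.DataFrame(rows)
    df["baseline_date"] = pd.to_datetime(df["baseline_date"])
    for c in ("followup_end_date", "death_date"):
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


IHD = DiseaseDefinition("ihd", expand_code_range("I20", "I25"))


def test_definition_validation():
    with pytest.raises(ValueError, match="prefix"):
        DiseaseDefinition("bad", ("I2",))
    with pytest.raises(ValueError):
        DiseaseDefinition("empty", ())
    assert expand_code_range("I20", "I25") == ("I20", "I21", "I22", "I23", "I24", "I25")


def test_event_at_baseline_is_prevalent():
    part = _participants(
        [{"id": "a", "baseline_date": "2008-01-01", "followup_end_date": "2018-01-01"}]
    )
    events = pd.DataFrame({"id": ["a"], "code": ["I251"], "date": ["2008-01-01"],
                           "source": ["hospital"]})
    dt = derive_disease_status(events, part, [IHD], censor_date="2020-01-01")
    row = dt.iloc[0]
    assert row["prevalent"] and not row["incident"] and not row["at_risk"]


def test_event_after_baseline_is_incident_with_time():
    part = _participants(
        [{"id": "a", "baseline_date": "2008-01-01", "followup_end_date": "2018-01-01"}]
    )
    events = pd.DataFrame({"id": ["a"], "code": ["I21"], "date": ["2010-01-01"],
                           "source": ["hospital"]})
    dt = derive_disease_status(events, part, [IHD], censor_date="2020-01-01")
    row = dt.iloc[0]
    assert row["incident"] and row["event"] == 1
    assert row["time_years"] == pytest.approx(2.0, abs=0.01)


def test_censoring_takes_earliest_of_death_followup_and_censor_date():
    part = _participants(
        [
            {
                "id": "a",
                "baseline_date": "2008-01-01",
                "followup_end_date": "2019-01-01",
                "death_date": "2012-04-20",  # ~4.3 years in
            }
        ]
    )
    events = pd.DataFrame(columns=["id", "code", "date", "source"])
    dt = derive_disease_status(events, part, [IHD], censor_date="2018-01-01")
    row = dt.iloc[0]
    assert row["event"] == 0 and not row["prevalent"]
    assert row["time_years"] == pytest.approx(4.3, abs=0.05)


def test_unmatched_codes_ignored_and_post_censor_events_dropped():
    part = _participants(
        [{"id": "a", "baseline_date": "2008-01-01", "followup_end_date": "2010-01-01"}]
    )
    events = pd.DataFrame(
        {
            "id": ["a", "a"],
            "code": ["Z99", "I21"],
            "date": ["2009-01-01", "2015-06-01"],  # I21 falls after follow-up end
            "source": ["hospital", "hospital"],
        }
    )
    dt = derive_disease_status(events, part, [IHD], censor_date="2020-01-01")
    row = dt.iloc[0]
    assert not row["prevalent"] and not row["incident"]
    assert row["time_years"] == pytest.approx(2.0, abs=0.01)


def test_prevalent_incident_never_partition(small_cohort):
    dt = derive_disease_status(
        small_cohort.events, small_cohort.participants, default_definitions()
    )
    n = len(small_cohort.participants)
    for _, g in dt.groupby("disease"):
        prevalent = int(g["prevalent"].sum())
        incident = int(g["incident"].sum())
        never = int((~g["prevalent"] & ~g["incident"]).sum())
        assert prevalent + incident + never == n
        assert not (g["prevalent"] & g["incident"]).any()


def test_unadjusted_2x2_or_matches_cross_product():
    """a=20, b=80, c=10, d=90 -> OR = (20*90)/(80*10) = 2.25 to 1e-6."""
    n_g, n_r = 100, 100
    ids = [f"g{i}" for i in range(n_g)] + [f"r{i}" for i in range(n_r)]
    prevalent = [True] * 20 + [False] * 80 + [True] * 10 + [False] * 90
    dt = pd.DataFrame(
        {
            "id": ids, "disease": "ihd", "prevalent": prevalent,
            "incident": False, "time_years": 10.0, "event": 0,
            "at_risk": [not p for p in prevalent],
        }
    )
    subgroup_of = pd.Series(["G"] * n_g + ["R"] * n_r, index=ids)
    covars = pd.DataFrame(
        {"age": 55.0, "sex": "female", "center": "C1"}, index=pd.Index(ids, name="id")
    )
    res = prevalence_odds_ratios(dt, subgroup_of, covars, reference="R")
    row = res[res["subgroup"] == "G"].iloc[0]
    assert row["estimate"] == pytest.approx(2.25, abs=1e-6)
    ref = res[res["subgroup"] == "R"].iloc[0]
    assert ref["estimate"] == 1.0


def test_zero_case_outcome_reported_non_estimable():
    ids = [f"p{i}" for i in range(40)]
    dt = pd.DataFrame(
        {
            "id": ids, "disease": "stroke", "prevalent": False,
            "incident": False, "time_years": 5.0, "event": 0, "at_risk": True,
        }
    )
    subgroup_of = pd.Series(["A"] * 20 + ["B"] * 20, index=ids)
    covars = pd.DataFrame({"age": 60.0, "sex": "male", "center": "C1"},
                          index=pd.Index(ids, name="id"))
    res = prevalence_odds_ratios(dt, subgroup_of, covars, reference="B")
    row = res[res["subgroup"] == "A"].iloc[0]
    assert np.isnan(row["estimate"]) and "non-estimable" in row["note"]
    res_hr = incidence_hazard_ratios(dt, subgroup_of, covars, reference="B")
    row = res_hr[res_hr["subgroup"] == "A"].iloc[0]
    assert np.isnan(row["estimate"]) and "non-estimable" in row["note"]


def _simulate_cox_panel(rng, n=4000, log_hr=np.log(2.0)):
    ids = [f"p{i}" for i in range(n)]
    group = rng.uniform(size=n) < 0.5
    rate = 0.009 * np.exp(log_hr * group)
    t = rng.exponential(1.0 / rate)
    cens = rng.uniform(8, 12, n)
    event = t <= cens
    time = np.minimum(t, cens)
    dt = pd.DataFrame(
        {
            "id": ids, "disease": "ihd", "prevalent": False, "incident": event,
            "time_years": time, "event": event.astype(int), "at_risk": True,
        }
    )
    subgroup_of = pd.Series(np.where(group, "G", "R"), index=ids)
    covars = pd.DataFrame(
        {
            "age": rng.uniform(40, 70, n),
            "sex": rng.choice(["female", "male"], n),
            "center": rng.choice(["C1", "C2", "C3"], n),
        },
        index=pd.Index(ids, name="id"),
    )
    return dt, subgroup_of, covars


def test_planted_hazard_ratio_recovered():
    rng = np.random.default_rng(10)
    dt, subgroup_of, covars = _simulate_cox_panel(rng)
    res = incidence_hazard_ratios(dt, subgroup_of, covars, reference="R")
    row = res[res["subgroup"] == "G"].iloc[0]
    assert 1.6 < row["estimate"] < 2.5
    assert row["ci_low"] <= 2.0 <= row["ci_high"]


def test_hazard_ratio_scale_invariance():
    rng = np.random.default_rng(11)
    dt, subgroup_of, covars = _simulate_cox_panel(rng, n=1500)
    res1 = incidence_hazard_ratios(dt, subgroup_of, covars, reference="R")
    dt2 = dt.copy()
    dt2["time_years"] *= 2.0
    res2 = incidence_hazard_ratios(dt2, subgroup_of, covars, reference="R")
    assert res1[res1["subgroup"] == "G"]["estimate"].iloc[0] == pytest.approx(
        res2[res2["subgroup"] == "G"]["estimate"].iloc[0], rel=1e-6
    )


def test_incidence_rate_hand_sums():
    ids = ["a", "b", "c"]
    dt = pd.DataFrame(
        {
            "id": ids, "disease": "ihd", "prevalent": False,
            "incident": [True, False, True], "time_years": [2.0, 3.0, 5.0],
            "event": [1, 0, 1], "at_risk": True,
        }
    )
    sub = pd.Series(["S", "S", "S"], index=ids)
    res = incidence_rates(dt, sub)
    assert res["rate_per_1000py"].iloc[0] == pytest.approx(200.0)
    # zero-event subgroup
    dt["event"] = 0
    dt["incident"] = False
    assert incidence_rates(dt, sub)["rate_per_1000py"].iloc[0] == 0.0


def test_binary_panel_matches_disease_table(small_cohort):
    dt = derive_disease_status(
        small_cohort.events, small_cohort.participants, default_definitions()
    )
    panel = binary_panel(dt, "prevalent")
    assert list(panel.columns) == list(CARDIOMETABOLIC)
    assert panel.isin([0, 1]).all().all()
    for d in CARDIOMETABOLIC:
        expected = dt[dt["disease"] == d].set_index("id")["prevalent"].astype(int)
        pd.testing.assert_series_equal(
            panel[d].sort_index(), expected.sort_index(), check_names=False
        )


def test_definitions_yaml_roundtrip(tmp_path):
    defs = default_definitions()
    path = tmp_path / "defs.yaml"
    save_definitions(defs, path)
    back = load_definitions(path)
    assert {d.name: d.code_prefixes for d in back} == {
        d.name: d.code_prefixes for d in defs
    }
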