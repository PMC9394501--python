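"""Phenotype construction: Tukey filtering, medication adjustments,
hypertension/CAD classification, parental proxies, survival records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ykin import phenotypes as ph
from ykin.phenotypes import HealthRecord


# ---------------------------------------------------------------------------
# Tukey outlier removal


def tukey_oracle(values, k=3.0):
    """Independent fixed-point iteration over a plain python set of survivors."""
    vals = [v for v in values if not (v is None or np.isnan(v))]
    alive = list(vals)
    while True:
        q1, q3 = np.percentile(alive, [25, 75])
        iqr = q3 - q1
        nxt = [v for v in alive if q1 - k * iqr <= v <= q3 + k * iqr]
        if len(nxt) == len(alive):
            return set(alive)
        alive = nxt


def test_tukey_constant_vector_all_retained():
    mask = ph.tukey_filter([5.0] * 10)
    assert mask.all()


def test_tukey_single_outlier_two_passes():
    vals = list(range(1, 10)) + [1000.0]
    mask = ph.tukey_filter(vals)
    assert mask.tolist() == [True] * 9 + [False]
    # survivors are a fixed point
    again = ph.tukey_filter([v for v, m in zip(vals, mask) if m])
    assert again.all()


def test_tukey_multipass_matches_oracle():
    # second outlier only exposed after the first is removed
    vals = np.array([10.0, 10.5, 11.0, 11.5, 12.0, 12.5, 13.0, 40.0, 4000.0])
    mask = ph.tukey_filter(vals)
    surv = set(np.asarray(vals)[mask.to_numpy(dtype=bool)])
    assert surv == tukey_oracle(vals)
    assert 4000.0 not in surv and 40.0 not in surv


def test_tukey_random_vectors_match_oracle():
    rng = np.random.default_rng(11)
    for i in range(60):
        n = rng.integers(8, 60)
        base = rng.normal(0, 1, size=n)
        n_out = rng.integers(0, 4)
        out = rng.choice([-1, 1], size=n_out) * rng.uniform(10, 1e4, size=n_out)
        vals = np.concatenate([base, out])
        rng.shuffle(vals)
        mask = ph.tukey_filter(vals)
        surv = set(vals[mask.to_numpy(dtype=bool)])
        assert surv == tukey_oracle(vals), f"vector {i}"


def test_tukey_preserves_missing_and_order_invariance():
    vals = [1.0, np.nan, 2.0, 3.0, 2.5, 1000.0]
    mask = ph.tukey_filter(vals)
    assert mask.isna().tolist() == [False, True, False, False, False, False]
    rev = ph.tukey_filter(vals[::-1])
    assert set(np.asarray(vals)[mask.fillna(False).to_numpy(dtype=bool)]) == \
        set(np.asarray(vals[::-1])[rev.fillna(False).to_numpy(dtype=bool)])


def test_tukey_few_values_warns_no_removal():
    with pytest.warns(UserWarning):
        mask = ph.tukey_filter([1.0, 2.0, 1e9])
    assert mask.all()


@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40))
def test_tukey_idempotent(vals):
    mask = ph.tukey_filter(vals)
    surv = [v for v, m in zip(vals, mask) if m]
    if len(surv) >= 4:
        assert ph.tukey_filter(surv).all()


# ---------------------------------------------------------------------------
# blood pressure


def test_bp_medication_adjustment():
    sbp, dbp = ph.adjust_blood_pressure([120, 120], [80, 80], [True, False])
    assert sbp.tolist() == [135, 120]
    assert dbp.tolist() == [90, 80]


def test_bp_adjustment_difference_is_constant():
    rng = np.random.default_rng(0)
    s = rng.uniform(90, 200, 50)
    d = rng.uniform(50, 110, 50)
    sa, da = ph.adjust_blood_pressure(s, d, np.ones(50, dtype=bool))
    assert np.allclose(sa - s, 15) and np.allclose(da - d, 10)


def test_map_standard():
    assert ph.mean_arterial_pressure(120, 90) == pytest.approx(100)
    assert ph.mean_arterial_pressure(117, 117) == pytest.approx(117)


def test_map_printed_formula_exceeds_sbp():
    v = ph.mean_arterial_pressure(120, 80, formula="printed")
    assert v == pytest.approx(146.6667, abs=1e-3)
    assert v > 120  # physiologically implausible, flagged mode


def test_hypertension_thresholds_closed():
    assert ph.classify_hypertension([140], [70], [False])[0] == True  # noqa: E712
    assert ph.classify_hypertension([139], [89], [False])[0] == False  # noqa: E712
    assert ph.classify_hypertension([100], [60], [True])[0] == True  # noqa: E712
    assert ph.classify_hypertension([100], [90], [False])[0] == True  # noqa: E712


def test_hypertension_missing_input_missing_outcome():
    out = ph.classify_hypertension([np.nan], [80], [False])
    assert out.isna().all()


def test_hypertension_monotone_in_medication():
    rng = np.random.default_rng(1)
    s = rng.uniform(100, 180, 500)
    d = rng.uniform(60, 100, 500)
    base = ph.classify_hypertension(s, d, np.zeros(500, dtype=bool)).sum()
    med = rng.uniform(size=500) < 0.3
    more = ph.classify_hypertension(s, d, med).sum()
    assert more >= base


# ---------------------------------------------------------------------------
# lipids


def test_lipid_divisors():
    out = ph.adjust_lipids([5.6], [3.5], [1.4], [1.5], [True], apply_tukey=False)
    assert out["ldl"].iloc[0] == pytest.approx(5.0)
    assert out["total_chol"].iloc[0] == pytest.approx(7.0)
    assert out["log_trig"].iloc[0] == pytest.approx(np.log(1.5))


def test_lipids_unmedicated_identity():
    out = ph.adjust_lipids([5.6], [3.5], [1.4], [1.5], [False], apply_tukey=False)
    assert out["ldl"].iloc[0] == pytest.approx(3.5)
    assert out["total_chol"].iloc[0] == pytest.approx(5.6)


def test_nonpositive_triglyceride_becomes_missing():
    out = ph.adjust_lipids([5.0], [3.0], [1.4], [0.0], [False], apply_tukey=False)
    assert np.isnan(out["log_trig"].iloc[0])


# ---------------------------------------------------------------------------
# code lists / CAD


def test_icd_range_expansion():
    assert ph.expand_code_range("I21-I23") == ["I21", "I22", "I23"]
    assert ph.expand_code_range("K40-K46") == [f"K4{i}" for i in range(7)]
    assert ph.expand_code_range("I25.2") == ["I252"]


def test_cad_mi_range_code_is_case():
    assert ph.classify_cad([HealthRecord("hospital_icd10", "I22")]) == "case"
    assert ph.classify_cad([HealthRecord("hospital_icd10", "I21.4")]) == "case"


def test_cad_angina_only_is_excluded():
    assert ph.classify_cad([HealthRecord("hospital_icd10", "I20.0")]) == "excluded"
    assert ph.classify_cad([HealthRecord("hospital_icd9", "4139")]) == "excluded"


def test_cad_empty_is_control():
    assert ph.classify_cad([]) == "control"


def test_cad_case_takes_precedence_over_exclusion():
    recs = [HealthRecord("hospital_icd10", "I20.0"),
            HealthRecord("hospital_icd10", "I21.9")]
    assert ph.classify_cad(recs) == "case"


def test_cad_death_record_source_specific():
    # I20 qualifies as a case only on the death record list
    assert ph.classify_cad([HealthRecord("death_icd10_primary_or_secondary", "I20.5")]) == "case"
    assert ph.classify_cad([HealthRecord("hospital_icd10", "I20.5")]) == "control"


def test_cad_exclusion_medication():
    cl = ph.load_codelists()
    code = next(iter(cl["exclusion_med_codes"]))
    assert ph.classify_cad([], meds=[code]) == "excluded"


def test_cad_opcs_codes():
    assert ph.classify_cad([HealthRecord("operation_opcs", "K49.1")]) == "case"
    assert ph.classify_cad([HealthRecord("operation_opcs", "K75")]) == "case"
    assert ph.classify_cad([HealthRecord("operation_opcs", "K47")]) == "control"


def test_cad_cohort_partition_exhaustive(small_sim):
    cfg, sim = small_sim
    status = ph.classify_cad_cohort(sim.records, sim.meds, list(sim.cohort.index))
    counts = status.value_counts()
    assert counts.sum() == len(sim.cohort)
    assert set(counts.index) <= {"case", "control", "excluded"}
    # classification recovers the generative truth exactly (codes are faithful)
    assert ((status == "case") == sim.cohort["cad_true"]).all()


# ---------------------------------------------------------------------------
# parental phenotypes and survival


def _reports(rows):
    return pd.DataFrame(rows, columns=["father_conditions", "mother_conditions",
                                       "father_age", "mother_age",
                                       "father_dead", "mother_dead"])


def test_parent_selextions_map_to_case_control_missing():
    rep = _reports([
        [("heart_disease",), (), 70, 68, False, False],
        [(), ("high_blood_pressure",), 75, 74, False, False],
        [None, None, 80, 79, False, False],
    ])
    out = ph.build_parent_phenotypes(rep)
    assert out["father_cad"].tolist()[0] == True  # noqa: E712
    assert out["father_cad"].tolist()[1] == False  # noqa: E712
    assert pd.isna(out["father_cad"].iloc[2])
    assert out["mother_hypertension"].tolist()[1] == True  # noqa: E712


def test_parent_death_before_40_excluded_from_survival():
    rep = _reports([
        [(), (), 38, 70, True, False],   # father died at 38 -> excluded
        [(), (), 41, 70, True, False],   # father died at 41 -> kept
    ])
    out = ph.build_parent_phenotypes(rep)
    assert pd.isna(out["father_event_age"].iloc[0])
    assert pd.isna(out["father_dead"].iloc[0])
    assert out["father_event_age"].iloc[1] == 41
    assert out["father_dead"].iloc[1] == True  # noqa: E712
    # mother survival untouched by father exclusion
    assert out["mother_event_age"].notna().all()


def test_survival_record_event_after_entry():
    rec = ph.build_survival_records([60.0, 55.0], [2008.0, 2009.0],
                                    death_date=[2015.0, None])
    assert rec["dead"].tolist() == [True, False]
    assert rec["event_age"].iloc[0] == pytest.approx(67.0)
    # censored at the cohort-wide date (2021-11-01)
    assert rec["event_age"].iloc[1] == pytest.approx(55 + (2021.835 - 2009.0), abs=0.01)
    assert (rec["event_age"] >= rec["entry_age"]).all()
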