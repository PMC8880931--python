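"""Synthetic cohort generator: contracts, determinism, label realizability."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from pclr.errors import CohortFormatError, InvalidSamplingRateError
from pclr.synthetic import (HYPERTROPHY_THRESHOLD, LEAD_NAMES, CohortParams,
                            generate_cohort, read_cohort, visit_template,
                            wave_params, write_cohort)


def test_counting_contract():
    cohort = generate_cohort(2, 2, seed=7)
    assert len(cohort) == 2
    assert cohort.n_records == 4
    for rec in cohort.all_records():
        assert set(rec.leads) == set(LEAD_NAMES)
        for arr in rec.leads.values():
            assert arr.shape[0] == 10 * rec.sampling_rate
            assert arr.dtype == np.int16


def test_seed_determinism():
    a = generate_cohort(4, (1, 3), seed=11)
    b = generate_cohort(4, (1, 3), seed=11)
    c = generate_cohort(4, (1, 3), seed=12)
    for ra, rb in zip(a.all_records(), b.all_records()):
        assert ra.record_id == rb.record_id
        for lead in LEAD_NAMES:
            assert np.array_equal(ra.leads[lead], rb.leads[lead])
    assert any(not np.array_equal(ra.leads["I"], rc.leads["I"])
               for ra, rc in zip(a.all_records(), c.all_records()))


def test_noiseless_record_is_exactly_periodic(clean_params):
    """60 bpm, 250 Hz, no noise: every beat repeats the template exactly."""
    cohort = generate_cohort(1, 2, seed=3, params=clean_params)
    rec = cohort.groups[0].records[0]
    for lead in LEAD_NAMES:
        x = rec.leads[lead]
        assert np.array_equal(x[:-250], x[250:])


def test_invalid_sampling_rate_rejected():
    with pytest.raises(InvalidSamplingRateError):
        CohortParams(sampling_rates=(300,))


def test_bad_patient_count():
    with pytest.raises(ValueError):
        generate_cohort(0, 2, seed=0)
    with pytest.raises(ValueError):
        generate_cohort(2, 0, seed=0)


def test_age_advances_with_acquisition_day(small_cohort):
    for g in small_cohort:
        base = g.signature.baseline_age
        for rec in g.records:
            expected = base + rec.acquisition_day / 365.25
            assert rec.labels["age"] == pytest.approx(expected)


def test_hypertrophy_label_is_deterministic_threshold(small_cohort):
    for g in small_cohort:
        sig = g.signature
        assert sig.hypertrophy_like == (
            sig.amplitude_scale > HYPERTROPHY_THRESHOLD)


def test_af_contract():
    """AF visits have zero P amplitude and RR-interval CV >= 0.15."""
    params = CohortParams(af_carrier_fraction=1.0,
                          af_propensity_range=(1.0, 1.0))
    cohort = generate_cohort(8, 2, seed=21, params=params)
    n_af = 0
    for g in cohort:
        assert wave_params(g.signature, af_active=True)["P"][0] == 0.0
        for rec in g.records:
            assert rec.labels["af_active"] == 1
            rr = rec.meta["rr_intervals"]
            assert rr.std() / rr.mean() >= 0.15
            n_af += 1
    assert n_af == 16


def test_patient_separability():
    """Same-patient beat templates are closer than cross-patient ones."""
    cohort = generate_cohort(50, 2, seed=5)
    temps = []
    for g in cohort:
        hrs = [r.labels["heart_rate"] for r in g.records[:2]]
        temps.append([visit_template(g.signature, hr) for hr in hrs])
    within = [np.linalg.norm(t[0] - t[1]) for t in temps]
    across = [np.linalg.norm(temps[i][0] - temps[j][0])
              for i in range(50) for j in range(i + 1, 50)]
    assert np.mean(within) < np.mean(across)


def test_hypertrophy_linearly_recoverable():
    """R-amplitude features of the clean template separate the
    hypertrophy-like flag with AUC > 0.95."""
    cohort = generate_cohort(200, 1, seed=9)
    X, y = [], []
    for g in cohort:
        t = visit_template(g.signature, 60.0)
        X.append(np.abs(t).max(axis=0))        # per-lead peak amplitude
        y.append(int(g.signature.hypertrophy_like))
    X, y = np.array(X), np.array(y)
    model = LogisticRegression(max_iter=2000).fit(X[:100], y[:100])
    auc = roc_auc_score(y[100:], model.decision_function(X[100:]))
    assert auc > 0.95


def test_write_read_round_trip(tmp_path, small_cohort):
    path = str(tmp_path / "cohort")
    write_cohort(small_cohort, path)
    back = read_cohort(path)
    assert back.n_records == small_cohort.n_records
    orig = {r.record_id: r for r in small_cohort.all_records()}
    for rec in back.all_records():
        o = orig[rec.record_id]
        assert rec.patient_id == o.patient_id
        assert rec.sampling_rate == o.sampling_rate
        assert rec.acquisition_day == pytest.approx(o.acquisition_day)
        for k in ("age", "sex_like", "hypertrophy_like", "af_active",
                  "heart_rate"):
            assert rec.labels[k] == pytest.approx(o.labels[k])
        for lead in LEAD_NAMES:
            assert np.array_equal(rec.leads[lead], o.leads[lead])


def test_read_missing_lead_names_record(tmp_path, small_cohort):
    import h5py
    path = str(tmp_path / "cohort")
    write_cohort(small_cohort, path)
    rid = small_cohort.groups[0].records[0].record_id
    with h5py.File(f"{path}/cohort.h5", "r+") as f:
        del f[rid]["V3"]
    with pytest.raises(CohortFormatError, match=f"{rid}.*V3"):
        read_cohort(path)


def test_read_inconsistent_metadata(tmp_path, small_cohort):
    import pandas as pd
    path = str(tmp_path / "cohort")
    write_cohort(small_cohort, path)
    meta = pd.read_csv(f"{path}/metadata.csv")
    meta.loc[0, "patient_id"] = "PXXXXX"
    meta.to_csv(f"{path}/metadata.csv", index=False)
    with pytest.raises(CohortFormatError, match="patient_id"):
        read_cohort(path)

    # a metadata row pointing at a record with no amplitude group
    meta = pd.read_csv(f"{path}/metadata.csv")
    meta.loc[0, "patient_id"] = small_cohort.groups[0].patient_id
    meta.loc[0, "record_id"] = "GHOST"
    meta.to_csv(f"{path}/metadata.csv", index=False)
    with pytest.raises(CohortFormatError, match="GHOST"):
        read_cohort(path)
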