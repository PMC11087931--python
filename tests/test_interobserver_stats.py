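"""Mixed-model fits vs statsmodels/OLS oracles; SD summaries; multiplicity."""

import numpy as np
import pandas as pd
import pytest

from caaseg.errors import ParameterError, ValidationError
from caaseg.interobserver_stats import (
    fit_lmm,
    lrt_contour_type,
    multiplicity_adjust,
    observer_sd_summary,
    validate_metric_table,
)


def simulate_table(n_patients=10, beta1=0.4, sigma_b=0.3, sigma=0.2, seed=0, metric="msd_mm"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        b = rng.normal(0, sigma_b)
        for j in range(3):
            rows.append(
                dict(patient=f"p{i:02d}", contour_type="manual", observer=f"obs{j + 1}",
                     metric=metric, value=1.0 + b + rng.normal(0, sigma))
            )
        rows.append(
            dict(patient=f"p{i:02d}", contour_type="auto", observer="auto",
                 metric=metric, value=1.0 + beta1 + b + rng.normal(0, sigma))
        )
    return pd.DataFrame(rows)


def test_matches_statsmodels_ml_fit():
    import statsmodels.formula.api as smf

    table = simulate_table(seed=42)
    fit = fit_lmm(table, "msd_mm")
    sm_fit = smf.mixedlm(
        "value ~ C(contour_type, Treatment('manual'))", table, groups=table["patient"]
    ).fit(reml=False)
    assert fit.beta0 == pytest.approx(sm_fit.params.iloc[0], abs=1e-5)
    assert fit.beta1 == pytest.approx(sm_fit.params.iloc[1], abs=1e-5)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
    assert fit.sigma == pytest.approx(np.sqrt(sm_fit.scale), abs=1e-4)
    assert fit.sigma_b == pytest.approx(np.sqrt(float(sm_fit.cov_re.iloc[0, 0])), abs=1e-4)


def test_zero_between_patient_variance_matches_ols():
    table = simulate_table(sigma_b=0.0, seed=7)
    fit = fit_lmm(table, "msd_mm")
    x = np.column_stack(
        [np.ones(len(table)), (table["contour_type"] == "auto").astype(float)]
    )
    beta_ols = np.linalg.lstsq(x, table["value"].to_numpy(), rcond=None)[0]
    assert fit.beta0 == pytest.approx(beta_ols[0], abs=1e-6)
    assert fit.beta1 == pytest.approx(beta_ols[1], abs=1e-6)


def test_patient_labels_exchangeable():
    table = simulate_table(seed=3)
    relabel = {f"p{i:02d}": f"q{(i * 7) % 10:02d}" for i in range(10)}
    shuffled = table.assign(patient=table["patient"].map(relabel))
    f1 = fit_lmm(table, "msd_mm")
    f2 = fit_lmm(shuffled, "msd_mm")
    assert f1.beta1 == pytest.approx(f2.beta1, abs=1e-10)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)


def test_full_likelihood_dominates_reduced():
    table = simulate_table(seed=11)
    full = fit_lmm(table, "msd_mm")
    reduced = fit_lmm(table, "msd_mm", use_type_effect=False)
    assert full.loglik >= reduced.loglik - 1e-6
    lrt = lrt_contour_type(full, reduced)
    assert 0.0 <= lrt.p_value <= 1.0


def test_zero_effect_constant_data_gives_p_one():
    rows = []
    for i in range(5):
        for obs, ctype in (("obs1", "manual"), ("obs2", "manual"), ("auto", "auto")):
            rows.append(dict(patient=f"p{i}", contour_type=ctype, observer=obs,
                             metric="dsc", value=1.0))
    table = pd.DataFrame(rows)
    full = fit_lmm(table, "dsc")
    reduced = fit_lmm(table, "dsc", use_type_effect=False)
    lrt = lrt_contour_type(full, reduced)
    assert lrt.statistic == pytest.approx(0.0, abs=1e-6)
    assert lrt.p_value == pytest.approx(1.0, abs=1e-6)


def test_single_patient_rejected():
    table = simulate_table(n_patients=1)
    with pytest.raises(ParameterError):
        fit_lmm(table, "msd_mm")


def test_sd_summary_hand_cases():
    t = pd.DataFrame(
        [
            dict(patient="a", contour_type="manual", observer="o1", metric="m", value=1.0),
            dict(patient="a", contour_type="manual", observer="o2", metric="m", value=3.0),
            dict(patient="b", contour_type="manual", observer="o1", metric="m", value=0.0),
            dict(patient="b", contour_type="manual", observer="o2", metric="m", value=0.0),
        ]
    )
    # patient a: sample SD of (1, 3) = sqrt(2); patient b: 0 -> mean sqrt(2)/2
    assert observer_sd_summary(t, "m") == pytest.approx((np.sqrt(2.0) + 0.0) / 2.0)


def test_sd_summary_excludes_single_observer_patient():
    t = pd.DataFrame(
        [
            dict(patient="a", contour_type="manual", observer="o1", metric="m", value=1.0),
            dict(patient="a", contour_type="manual", observer="o2", metric="m", value=3.0),
            dict(patient="b", contour_type="manual", observer="o1", metric="m", value=9.0),
        ]
    )
    with pytest.warns(UserWarning, match="b"):
        assert observer_sd_summary(t, "m") == pytest.approx(np.sqrt(2.0))


def test_identical_observers_give_zero_sd():
    t = simulate_table(sigma=0.0, sigma_b=0.0, seed=1)
    assert observer_sd_summary(t, "msd_mm") == pytest.approx(0.0, abs=1e-12)


def test_bonferroni_hand_value():
    assert multiplicity_adjust(np.repeat(0.012, 22), "bonferroni")[0] == pytest.approx(0.264)
    assert multiplicity_adjust([0.012], "bonferroni")[0] == pytest.approx(0.012)


def test_holm_dominates_bonferroni(rng):
    for _ in range(20):
        p = rng.random(rng.integers(1, 12))
        holm = multiplicity_adjust(p, "holm")
        bonf = multiplicity_adjust(p, "bonferroni")
        assert (holm <= bonf + 1e-12).all()
        assert (holm >= p - 1e-12).all()


def test_holm_against_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(9)
    ours = multiplicity_adjust(p, "holm")
    theirs = multipletests(p, method="holm")[1]
    assert np.allclose(ours, theirs, atol=1e-12)


def test_invalid_pvalues_rejected():
    with pytest.raises(ParameterError):
        multiplicity_adjust([0.5, 1.2], "holm")


def test_table_contract_enforced():
    bad = pd.DataFrame([dict(patient="a", contour_type="robot", observer="o", metric="m", value=1.0)])
    with pytest.raises(ValidationError):
        validate_metric_table(bad)
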