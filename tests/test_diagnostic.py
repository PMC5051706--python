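"""Logistic adjustment, AUROC vs a pair-counting oracle, paired comparison,
intention-to-diagnose and presumed prevalence."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from elastoconcord import (
    Device,
    GeneratorConfig,
    PopulationLabel,
    auroc,
    compare_auroc_paired,
    derive_populations,
    fit_logistic,
    itd_analysis,
    presumed_prevalence,
)
from elastoconcord.diagnostic import Combiner

from conftest import analysis_ready


def auroc_oracle(scores, y):
    """Brute-force pair counting with ties worth 1/2."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- logistic


def test_logistic_two_by_two_recovers_log_odds_ratio():
    y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
    x = np.array([1] * 30 + [0] * 30)
    model = fit_logistic(y, pd.DataFrame({"exposed": x}))
    assert model.converged
    assert model.params["exposed"] == pytest.approx(np.log(4), abs=1e-6)


def test_logistic_intercept_only_closed_form(rng):
    y = (rng.random(200) < 0.3).astype(int)
    model = fit_logistic(y, pd.DataFrame(index=range(200)))
    assert model.params["const"] == pytest.approx(logit(y.mean()), abs=1e-8)


def test_logistic_null_slopes_rarely_significant():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        y = (rng.random(500) < 0.4).astype(int)
        X = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        model = fit_logistic(y, X)
        hits += bool((model.zvalues.drop("const").abs() < 2).all())
    assert hits >= 8


def test_logistic_rejects_bad_inputs(rng):
    y = (rng.random(50) < 0.5).astype(int)
    x = rng.normal(size=50)
    with pytest.raises(ValueError, match="binary"):
        fit_logistic(y + 5, pd.DataFrame({"x": x}))
    with pytest.raises(ValueError, match="singular"):
        fit_logistic(y, pd.DataFrame({"x": x, "x2": 2 * x}))


def test_logistic_perfect_separation_flagged():
    y = np.array([0] * 25 + [1] * 25)
    x = np.arange(50.0)
    model = fit_logistic(y, pd.DataFrame({"x": x}))
    assert not model.converged


def test_informative_covariate_never_lowers_in_sample_auroc(rng):
    n = 300
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(x1 + 0.8 * x2)))
    y = (rng.random(n) < p).astype(int)
    base = fit_logistic(y, pd.DataFrame({"x1": x1}))
    full = fit_logistic(y, pd.DataFrame({"x1": x1, "x2": x2}))
    a_base = auroc(base.linear_predictor, y).auroc
    a_full = auroc(full.linear_predictor, y).auroc
    assert a_full >= a_base - 1e-9


# ---------------------------------------------------------------- AUROC


def test_auroc_worked_examples():
    assert auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auroc == 1.0
    res = auroc([0.9, 0.8, 0.7, 0.8], [1, 1, 0, 0])
    assert res.auroc == pytest.approx(0.875)
    assert res.n_pos == 2 and res.n_neg == 2


def test_auroc_matches_brute_force_oracle(rng):
    for _ in range(40):
        n = int(rng.integers(4, 200))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        # discretized scores force ties
        scores = np.round(rng.normal(size=n) + y, 1)
        res = auroc(scores, y)
        assert res.auroc == pytest.approx(auroc_oracle(scores, y), abs=1e-12)
        assert 0 <= res.ci_low <= res.auroc <= res.ci_high <= 1


def test_auroc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    y = rng.integers(0, 2, 150)
    y[:2] = [0, 1]
    scores = rng.normal(size=150) + 0.8 * y
    assert auroc(scores, y).auroc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError, match="case and one control"):
        auroc([1.0, 2.0, 3.0], [1, 1, 1])


def test_null_auroc_near_half(rng):
    y = rng.integers(0, 2, 4000)
    scores = rng.normal(size=4000)
    assert auroc(scores, y).auroc == pytest.approx(0.5, abs=0.03)


# ------------------------------------------------------- paired comparison


def test_compare_self_is_null(rng):
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.normal(size=100)
    res = compare_auroc_paired(s, s, y)
    assert res.difference == 0.0 and res.z == 0.0 and res.p_value == 1.0


def test_compare_antisymmetric(rng):
    y = rng.integers(0, 2, 120)
    y[:2] = [0, 1]
    a = rng.normal(size=120) + y
    b = rng.normal(size=120)
    ab = compare_auroc_paired(a, b, y)
    ba = compare_auroc_paired(b, a, y)
    assert ab.difference == pytest.approx(-ba.difference)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_compare_detects_informative_vs_noise():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        informative = rng.normal(size=400) + 1.2 * y
        noise = rng.normal(size=400)
        hits += compare_auroc_paired(informative, noise, y).p_value < 0.01
    assert hits >= 19


def test_compare_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        compare_auroc_paired([1, 2], [1, 2, 3], [0, 1, 1])


# -------------------------------------------------- intention to diagnose


def test_itd_equals_per_protocol_when_everything_applicable():
    frame = analysis_ready(
        GeneratorConfig(
            n=400, seed=19, dead_signal_prob=0.0, swe_failure_prob=0.0,
            te_m_failure_intercept=-30.0, te_xl_failure_prob=0.0,
            te_m_noisy_prob=0.0, te_m_short_prob=0.0,
            te_xl_noisy_prob=0.0, te_xl_short_prob=0.0,
            ft_unreliable_prob=0.0, shot_sigma_log=0.05,
        )
    )
    res = itd_analysis(frame, Device.SWE)
    assert res["itd"] == res["per_protocol"]


def test_itd_all_missing_reduces_to_imputed_score(study_frame, study_populations):
    itd_pop = study_frame[
        study_frame["id"].isin(study_populations[PopulationLabel.INTENTION_TO_DIAGNOSE])
    ].copy()
    itd_pop["status_swe"] = "FAILURE"
    res = itd_analysis(itd_pop, Device.SWE)
    y = (itd_pop["fibrotest"] >= 0.58).astype(int)
    direct = auroc(1.0 - itd_pop["fibrotest"], y)
    assert res["itd"].auroc == pytest.approx(direct.auroc)


def test_worst_case_imputation_never_helps(study_frame, study_populations):
    """Randomly discarding measurements and imputing 1 - FibroTest can only
    lower the AUROC against the FibroTest-presumed endpoint."""
    itd_pop = study_frame[
        study_frame["id"].isin(study_populations[PopulationLabel.INTENTION_TO_DIAGNOSE])
    ].copy()
    itd_pop = itd_pop[itd_pop["std_elasticity_swe"].notna()]
    itd_pop["status_swe"] = "APPLICABLE"  # clean slate: PP on everyone
    baseline = itd_analysis(itd_pop, Device.SWE)["per_protocol"]
    rng = np.random.default_rng(2)
    drop = rng.random(len(itd_pop)) < 0.2
    itd_pop.loc[drop, "status_swe"] = "FAILURE"
    res = itd_analysis(itd_pop, Device.SWE)
    assert res["itd"].auroc <= baseline.auroc + 0.01


def test_itd_degenerate_endpoint_rejected(study_frame):
    with pytest.raises(ValueError, match="degenerate endpoint"):
        itd_analysis(study_frame, Device.SWE, ft_cutoff=2.0)


def test_itd_penalty_larger_for_bmi_dependent_failures(study_frame, study_populations):
    """TE-M failures concentrate in high-BMI patients, so its drop from
    per-protocol to intention-to-diagnose exceeds 2D-SWE's."""
    itd_pop = study_frame[
        study_frame["id"].isin(study_populations[PopulationLabel.INTENTION_TO_DIAGNOSE])
    ]
    swe = itd_analysis(itd_pop, Device.SWE)
    tem = itd_analysis(itd_pop, Device.TE_M)
    penalty_swe = swe["per_protocol"].auroc - swe["itd"].auroc
    penalty_tem = tem["per_protocol"].auroc - tem["itd"].auroc
    assert penalty_tem > penalty_swe


# ----------------------------------------------------- presumed prevalence


def test_prevalence_zero_when_all_below_cutoff(concordance_frame):
    res = presumed_prevalence(concordance_frame, [Device.SWE], stiffness_cutoff_kpa=1e6)
    assert res.rate == 0.0


def test_worst_of_three_dominates_single(concordance_frame):
    worst = presumed_prevalence(concordance_frame, list(Device), combiner=Combiner.WORST_OF_THREE)
    for dev in Device:
        single = presumed_prevalence(concordance_frame, [dev], combiner=Combiner.SINGLE)
        assert worst.rate >= single.rate - 1e-9


def test_concordant_only_below_worst_of_three(concordance_frame):
    worst = presumed_prevalence(concordance_frame, list(Device), combiner=Combiner.WORST_OF_THREE)
    conc = presumed_prevalence(concordance_frame, list(Device), combiner=Combiner.CONCORDANT_ONLY)
    assert conc.rate <= worst.rate
    assert conc.denominator <= worst.denominator
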