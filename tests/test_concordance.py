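"""Lin CCC against a direct-formula oracle, CI behaviour, comparisons and
stratified tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from elastoconcord import (
    Device,
    GeneratorConfig,
    PopulationLabel,
    StratificationScheme,
    StratVariable,
    compare_ccc_paired,
    derive_populations,
    lin_ccc,
    stratified_ccc_table,
)
from elastoconcord.concordance import ccc_estimate

from conftest import analysis_ready


def ccc_oracle(x, y):
    """Direct evaluation of Lin's formula, independent of the package path."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


finite_vec = arrays(
    float,
    st.integers(3, 40),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((0.1, 0.5, 0.9), (0.1, 0.5, 0.9), 1.0),
        ((1, 2, 3), (2, 3, 4), 4 / 7),
        ((1, 2, 3), (3, 2, 1), -1.0),  # oracle-verified
    ],
)
def test_ccc_worked_examples(x, y, expected):
    assert ccc_estimate(x, y) == pytest.approx(expected, abs=1e-12)
    assert ccc_oracle(x, y) == pytest.approx(expected, abs=1e-12)


def test_ccc_matches_oracle_on_random_vectors(rng):
    for _ in range(300):
        n = rng.integers(3, 200)
        x = rng.normal(size=n) * rng.uniform(0.1, 5)
        y = 0.5 * x + rng.normal(size=n) + rng.uniform(-2, 2)
        assert abs(ccc_estimate(x, y) - ccc_oracle(x, y)) < 1e-12


def test_degenerate_inputs_signalled():
    with pytest.raises(ZeroDivisionError):
        lin_ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="equal length"):
        lin_ccc([1, 2, 3], [1, 2])
    with pytest.raises(ValueError, match="n >= 3"):
        lin_ccc([1, 2], [1, 2])
    with pytest.raises(ValueError, match="finite"):
        lin_ccc([1, 2, np.nan], [1, 2, 3])
    # constant x vs varying y: defined, zero concordance
    assert ccc_estimate([2, 2, 2], [1, 2, 3]) == pytest.approx(0.0)


@settings(derandomize=True, deadline=None, max_examples=150)
@given(x=finite_vec, noise=finite_vec)
def test_ccc_bounded_by_pearson(x, noise):
    y = x + noise[: len(x)] if len(noise) >= len(x) else None
    if y is None:
        return
    if np.std(x) == 0 or np.std(y) == 0:
        return
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):
        return
    assert abs(ccc_estimate(x, y)) <= abs(r) + 1e-9


@settings(derandomize=True, deadline=None, max_examples=100)
@given(
    x=arrays(float, 20, elements=st.floats(-10, 10, width=32)),
    a=st.floats(0.1, 5),
    b=st.floats(-5, 5),
)
def test_ccc_invariant_to_common_affine_map(x, a, b):
    rng = np.random.default_rng(1)
    y = x + rng.normal(0, 1, size=len(x))
    assert ccc_estimate(a * x + b, a * y + b) == pytest.approx(ccc_estimate(x, y), abs=1e-9)


def test_ccc_penalizes_location_shift():
    x = np.linspace(0, 1, 50)
    assert lin_ccc(x, x + 0.3).estimate < 1.0
    assert lin_ccc(x, x).estimate == pytest.approx(1.0)


def test_ci_ordering_and_bounds():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 100)
    y = 0.8 * x + rng.normal(0, 0.5, 100)
    res = lin_ccc(x, y)
    assert -1 <= res.ci_low <= res.estimate <= res.ci_high <= 1
    assert res.n == 100


def test_compare_self_is_null(concordance_frame):
    res = compare_ccc_paired(
        concordance_frame, Device.SWE, Device.SWE, "fibrotest", n_boot=200, seed=4
    )
    assert res.difference == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_compare_requires_seed_and_enough_boot(concordance_frame):
    with pytest.raises(ValueError, match="n_boot"):
        compare_ccc_paired(concordance_frame, Device.SWE, Device.TE_M, "fibrotest", n_boot=50, seed=1)
    with pytest.raises(ValueError, match="seed"):
        compare_ccc_paired(concordance_frame, Device.SWE, Device.TE_M, "fibrotest", n_boot=200)


def test_compare_degenerate_cohort_warns():
    row = {
        "std_elasticity_swe": 0.4,
        "std_elasticity_te_m": 0.4,
        "fibrotest": 0.5,
    }
    frame = pd.DataFrame([row] * 31)
    res = compare_ccc_paired(frame, Device.SWE, Device.TE_M, "fibrotest", n_boot=200, seed=3)
    assert res.difference == 0.0
    assert res.warning is not None


def test_planted_device_contrast_detected_by_paired_bootstrap():
    """TE-M's larger inflammation inflation yields a significantly higher
    CCC with ActiTest than 2D-SWE in non-advanced fibrosis in >= 90% of
    seeded cohorts at n=1500."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        frame = analysis_ready(GeneratorConfig(n=1500, seed=7000 + seed))
        f012 = frame[frame["fibrotest"] < 0.58]
        res = compare_ccc_paired(f012, Device.TE_M, Device.SWE, "actitest", n_boot=500, seed=seed)
        hits += res.difference > 0 and res.p_value < 0.05
    assert hits >= 0.9 * n_seeds


def test_single_stratum_reduces_to_plain_ccc(concordance_frame):
    scheme = StratificationScheme(StratVariable.FIBROSIS, (), ("ALL",))
    table = stratified_ccc_table(concordance_frame, [Device.SWE], "fibrotest", scheme)
    assert len(table) == 1
    sub = concordance_frame[["std_elasticity_swe", "fibrotest"]].dropna()
    direct = lin_ccc(sub.iloc[:, 0], sub.iloc[:, 1])
    assert table.loc[0, "swe_ccc"] == pytest.approx(direct.estimate)


def test_scheme_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        StratificationScheme(StratVariable.FIBROSIS, (0.5, 0.5))
    with pytest.raises(ValueError, match="labels"):
        StratificationScheme(StratVariable.FIBROSIS, (0.5,), ("a", "a"))


def test_long_test_interval_lowers_concordance():
    """Planted interval effect: blood drawn long before elastography is a
    noisier reference, so concordance drops in the >30-day stratum."""
    frame = analysis_ready(GeneratorConfig(n=3000, seed=77, interval_long_prob=0.3))
    scheme = StratificationScheme(StratVariable.INTERVAL, (30.0,), ("short", "long"))
    table = stratified_ccc_table(frame, [Device.SWE, Device.TE_M], "fibrotest", scheme).set_index("stratum")
    for dev in ("swe", "te_m"):
        assert table.loc["long", f"{dev}_ccc"] < table.loc["short", f"{dev}_ccc"]


def test_activity_concordance_higher_in_advanced_fibrosis(concordance_frame):
    """Inflammation impacts elasticity more in F3F4 than F0F1F2 for every
    device under the default scenario."""
    scheme = StratificationScheme(StratVariable.FIBROSIS, (0.58,), ("F0F1F2", "F3F4"))
    table = stratified_ccc_table(
        concordance_frame, list(Device), "actitest", scheme
    ).set_index("stratum")
    for dev in Device:
        assert table.loc["F3F4", f"{dev.value}_ccc"] > table.loc["F0F1F2", f"{dev.value}_ccc"]
    # and TE-M is impacted more than 2D-SWE in non-advanced fibrosis
    assert table.loc["F0F1F2", "te_m_ccc"] > table.loc["F0F1F2", "swe_ccc"]


def test_small_strata_skipped(concordance_frame):
    scheme = StratificationScheme(StratVariable.FIBROSIS, (0.9999,), ("low", "high"))
    table = stratified_ccc_table(concordance_frame, [Device.SWE], "fibrotest", scheme)
    assert set(table["stratum"]) <= {"low", "high"}
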