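"""Subset comparisons, power/sample-size, correlations and curve fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.power import TTestPower

from scopeskill import analysis
from scopeskill.analysis import (
    FINAL,
    INITIAL,
    MIDDLE,
    SubsetSpec,
    compare_subsets,
    correlation_matrix,
    effect_summary,
    learning_curve,
    paired_power,
    paired_sample_size,
    subject_subset_means,
)
from scopeskill.errors import MissingTrialsError, NTooSmallError, ZeroVarianceError


def toy_table(values: dict, trials=(1, 2, 3, 14, 15, 16, 28, 29, 30)):
    """Metrics table with one metric column 'm' from {subject: {trial: v}}."""
    rows = []
    for subj, per_trial in values.items():
        for tr in trials:
            v = per_trial(tr) if callable(per_trial) else per_trial[tr]
            rows.append({"subject_id": subj, "trial_index": tr, "m": v})
    return pd.DataFrame(rows)


def normal_table(n_subjects, rng, mean=0.0, shift_final=0.0):
    vals = {}
    for i in range(n_subjects):
        draws = {tr: rng.normal(mean + (shift_final if tr >= 28 else 0.0), 1.0)
                 for tr in (1, 2, 3, 14, 15, 16, 28, 29, 30)}
        vals[f"S{i:03d}"] = draws
    return toy_table(vals)


# --------------------------------------------------------------------------
# subset means and effect summaries
# --------------------------------------------------------------------------

def test_subset_means_constant_and_simple():
    df = toy_table({"A": lambda tr: 5.0})
    out = subject_subset_means(df, INITIAL, metrics=["m"])
    assert out.loc["A", "m"] == 5.0
    df2 = toy_table({"A": {1: 4, 2: 5, 3: 6, 14: 0, 15: 0, 16: 0,
                           28: 0, 29: 0, 30: 0}})
    assert subject_subset_means(df2, INITIAL, ["m"]).loc["A", "m"] == 5.0


def test_subset_means_matches_groupby_oracle(rng):
    df = normal_table(12, rng)
    out = subject_subset_means(df, MIDDLE, ["m"])
    ref = (df[df.trial_index.isin([14, 15, 16])]
           .groupby("subject_id")["m"].mean())
    assert np.allclose(out["m"].to_numpy(), ref.sort_index().to_numpy())


def test_subset_means_missing_trials():
    df = normal_table(4, np.random.default_rng(0))
    df = df[~((df.subject_id == "S001") & (df.trial_index == 2))]
    with pytest.raises(MissingTrialsError) as exc:
        subject_subset_means(df, INITIAL, ["m"])
    assert "S001" in str(exc.value)


@pytest.mark.parametrize("mean_a, mean_b, ratio, diff", [
    (157.984, 81.648, 1.935, 76.336),   # execution time, initial vs final
    (78.553, 87.965, 0.893, -9.412),    # accuracy, initial vs final
    (1666.479, 887.263, 1.878, 779.216),  # tool translation
    (92.586, 81.648, 1.134, 10.938),    # execution time, middle vs final
])
def test_effect_summary_reported_gains(mean_a, mean_b, ratio, diff):
    """Gain ratios and differences of published subset means reproduce to
    printed precision."""
    r, d = effect_summary(mean_a, mean_b)
    assert r == pytest.approx(ratio, abs=5e-4)
    assert d == pytest.approx(diff, abs=5e-4)


def test_effect_summary_identity_and_divzero():
    assert effect_summary(3.0, 3.0) == (1.0, 0.0)
    with pytest.raises(ZeroDivisionError):
        effect_summary(1.0, 0.0)


# --------------------------------------------------------------------------
# paired comparison
# --------------------------------------------------------------------------

def test_all_zero_differences():
    df = toy_table({f"S{i}": lambda tr: 7.0 for i in range(6)})
    out = compare_subsets(df, INITIAL, FINAL, metrics=["m"]).iloc[0]
    assert out.t_stat == 0.0
    assert out.p_value == 1.0
    assert out.h == 0
    assert out.ci_low <= 0.0 <= out.ci_high
    assert not np.isfinite(out.sample_size)


def test_hand_computed_t_statistic():
    """Five subjects with known subset means: t equals dbar/(s_d/sqrt(n))."""
    ini = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
    fin = np.array([8.0, 9.0, 8.5, 10.0, 9.5])
    vals = {}
    for i, (a, b) in enumerate(zip(ini, fin)):
        vals[f"S{i}"] = {1: a, 2: a, 3: a, 14: 0, 15: 0, 16: 0,
                         28: b, 29: b, 30: b}
    out = compare_subsets(toy_table(vals), INITIAL, FINAL, metrics=["m"]).iloc[0]
    d = ini - fin
    t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(5))
    assert out.t_stat == pytest.approx(t_hand, abs=1e-12)
    t_scipy, p_scipy = stats.ttest_rel(ini, fin)
    assert out.t_stat == pytest.approx(t_scipy)
    assert out.p_value == pytest.approx(p_scipy)
    assert out.mean_a == pytest.approx(ini.mean())
    assert out.std_b == pytest.approx(fin.std(ddof=1))


def test_known_effect_simulation():
    """Differences ~ N(1,1) with n=80: p << 0.001 and power ~ 1."""
    rng = np.random.default_rng(5)
    df = normal_table(80, rng, mean=1.0, shift_final=-1.0)
    out = compare_subsets(df, INITIAL, FINAL, metrics=["m"]).iloc[0]
    assert out.p_value < 1e-3
    assert out.h == 1
    assert out.power > 0.99
    assert out.ci_low <= out["diff"] <= out.ci_high


def test_order_invariance(rng):
    df = normal_table(20, rng, shift_final=-0.4)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = compare_subsets(df, INITIAL, FINAL, metrics=["m"]).iloc[0]
    b = compare_subsets(shuffled, INITIAL, FINAL, metrics=["m"]).iloc[0]
    for col in ("t_stat", "p_value", "ci_low", "ci_high", "power"):
        assert a[col] == pytest.approx(b[col], abs=1e-12)


def test_too_few_subjects():
    df = normal_table(2, np.random.default_rng(0))
    with pytest.raises(NTooSmallError):
        compare_subsets(df, INITIAL, FINAL, metrics=["m"])


def test_holm_adjustment_is_conservative(rng):
    df = normal_table(20, rng, shift_final=-0.5)
    df["m2"] = rng.normal(size=len(df))
    raw = compare_subsets(df, INITIAL, FINAL, metrics=["m", "m2"])
    adj = compare_subsets(df, INITIAL, FINAL, metrics=["m", "m2"], holm=True)
    assert (adj["p_value_adj"] >= raw["p_value"] - 1e-15).all()


# --------------------------------------------------------------------------
# power and sample size
# --------------------------------------------------------------------------

def test_power_matches_statsmodels_oracle():
    sm = TTestPower()
    for d in (0.1, 0.3, 0.5, 0.8, 1.2):
        for n in (5, 10, 20, 40, 80):
            ref = sm.power(effect_size=d, nobs=n, alpha=0.05,
                           alternative="two-sided")
            assert paired_power(d, n) == pytest.approx(ref, abs=1e-6)


def test_power_monotone_in_n_and_effect():
    for d in (0.2, 0.5, 0.8):
        powers = [paired_power(d, n) for n in range(4, 200, 8)]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(powers, powers[1:]))
    for n in (10, 30, 80):
        powers = [paired_power(d, n) for d in np.linspace(0.05, 2.0, 25)]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(powers, powers[1:]))


def test_power_zero_effect_is_alpha():
    assert paired_power(0.0, 50, alpha=0.05) == pytest.approx(0.05, abs=1e-6)


def test_sample_size_is_smallest_sufficient_n():
    for d in (0.2, 0.45, 0.9):
        n = paired_sample_size(d)
        assert paired_power(d, int(n)) >= 0.8
        assert paired_power(d, int(n) - 1) < 0.8
    assert paired_sample_size(0.0) == math.inf


def test_sample_size_close_to_statsmodels():
    sm = TTestPower()
    for d in (0.25, 0.5, 1.0):
        ref = sm.solve_power(effect_size=d, power=0.8, alpha=0.05,
                             alternative="two-sided")
        assert abs(paired_sample_size(d) - math.ceil(ref)) <= 1


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def test_correlation_trivial_cases(rng):
    x = rng.normal(size=300)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x,
                       "d": rng.normal(size=300)})
    r, p = correlation_matrix(df.assign(trial_index=1, subject_id="s"),
                              metrics=["a", "b", "c", "d"])
    assert r.loc["a", "b"] == pytest.approx(1.0)
    assert r.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T)
    assert np.allclose(np.diag(r.to_numpy()), 1.0)
    assert r.to_numpy().min() >= -1.0 and r.to_numpy().max() <= 1.0


def test_correlation_null_simulation():
    rng = np.random.default_rng(17)
    df = pd.DataFrame(rng.normal(size=(2400, 2)), columns=["a", "b"])
    r, p = correlation_matrix(df, metrics=["a", "b"])
    assert abs(r.loc["a", "b"]) < 0.07
    assert p.loc["a", "b"] > 1e-4


def test_correlation_zero_variance():
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
    with pytest.raises(ZeroVarianceError):
        correlation_matrix(df, metrics=["a", "b"])


# --------------------------------------------------------------------------
# learning curves
# --------------------------------------------------------------------------

def test_learning_curve_exact_log_series():
    rows = [{"subject_id": "s", "trial_index": tr, "m": 10.0 - 2.0 * np.log(tr)}
            for tr in range(1, 31)]
    lc = learning_curve(pd.DataFrame(rows), "m")
    assert lc.intercept == pytest.approx(10.0, abs=1e-9)
    assert lc.slope == pytest.approx(-2.0, abs=1e-9)
    assert lc.r_squared == pytest.approx(1.0, abs=1e-12)
    assert (lc.per_trial["q1"] <= lc.per_trial["median"]).all()
    assert (lc.per_trial["median"] <= lc.per_trial["q3"]).all()


def test_learning_curve_constant_series():
    rows = [{"subject_id": "s", "trial_index": tr, "m": 3.0}
            for tr in range(1, 11)]
    lc = learning_curve(pd.DataFrame(rows), "m")
    assert lc.slope == pytest.approx(0.0, abs=1e-12)


def test_subset_spec_constants():
    assert INITIAL.trial_indices == (1, 2, 3)
    assert MIDDLE.trial_indices == (14, 15, 16)
    assert FINAL.trial_indices == (28, 29, 30)
    assert not (set(INITIAL.trial_indices) & set(MIDDLE.trial_indices)
                & set(FINAL.trial_indices))
    with pytest.raises(ValueError):
        SubsetSpec("bad", (1, 1, 2))
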