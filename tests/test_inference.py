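import numpy as np
import pandas as pd
import pytest

from tusmep.inference import (PowerSpec, accuracy_subgroup,
                              baseline_paired_tests, cohens_f_from_eta,
                              eta_from_F, fit_trial_lmm, overlap_regression,
                              required_sample_size, rm_anova, rm_anova_power)


# ------------------------------------------------------------ effect sizes

def test_eta_from_F():
    assert eta_from_F(21.19, 2, 28) == pytest.approx(0.602, abs=0.001)
    assert eta_from_F(0.0, 3, 14) == 0.0
    assert eta_from_F(1.0, 1, 10) == pytest.approx(1 / 11)
    with pytest.raises(ValueError):
        eta_from_F(1.0, 0, 10)


def test_cohens_f_from_eta():
    assert cohens_f_from_eta(0.0) == 0.0
    assert cohens_f_from_eta(0.5) == pytest.approx(1.0)
    assert cohens_f_from_eta(0.602) == pytest.approx(1.2299, abs=1e-3)
    with pytest.raises(ValueError):
        cohens_f_from_eta(1.0)


# ------------------------------------------------------------ paired tests

def test_baseline_paired_tests():
    rows = []
    diffs = [0.2, -0.1, 0.3, 0.0, 0.1]
    for i, d in enumerate(diffs):
        rows.append({"participant": i, "condition": "verum", "measure": "mep",
                     "value": 1.0 + d})
        rows.append({"participant": i, "condition": "sham", "measure": "mep",
                     "value": 1.0})
    res = baseline_paired_tests(pd.DataFrame(rows))
    r = res.iloc[0]
    assert r["t"] == pytest.approx(1.414, abs=1e-3)
    assert r["p"] == pytest.approx(0.230, abs=2e-3)
    assert r["df"] == 4


def test_baseline_paired_tests_degenerate():
    rows = []
    for i in range(3):
        rows.append({"participant": i, "condition": "verum", "measure": "m",
                     "value": 2.0})
        rows.append({"participant": i, "condition": "sham", "measure": "m",
                     "value": 1.0})
    res = baseline_paired_tests(pd.DataFrame(rows))
    assert res.iloc[0]["zero_variance"]
    same = pd.DataFrame(rows).assign(value=1.0)
    res = baseline_paired_tests(same)
    assert res.iloc[0]["t"] == 0.0 and res.iloc[0]["p"] == 1.0
    assert res.iloc[0]["cohens_d"] == 0.0


# ------------------------------------------------------------ LMM

def _lmm_fixture():
    """Seeded dataset with participant, condition-slope and cell effects."""
    rng = np.random.default_rng(7)
    rows = []
    for p in range(12):
        u = rng.normal(0, .3)
        vv = rng.normal(0, .15)
        for c in ["sham", "verum"]:
            for t in ["Baseline", "T5", "T30", "T60"]:
                b = rng.normal(0, .12)
                for _ in range(8):
                    y = 1 + u + (vv if c == "verum" else 0) + b \
                        + rng.normal(0, .4)
                    rows.append((p, c, t, y))
    return pd.DataFrame(rows, columns=["participant", "condition",
                                       "timepoint", "y"])


def test_lmm_satterthwaite_matches_lmerTest_reference():
    """Type III F-tests with Satterthwaite dfs against the lmerTest oracle.

    Reference values computed with R lmerTest on the identical dataset:
    lmer(y ~ condition*timepoint + (1+condition|participant)
         + (1|participant:cell)), anova(type=3, ddf="Satterthwaite").
    """
    fit = fit_trial_lmm(_lmm_fixture(), dv="y",
                        random_structure="condition+cell",
                        df_method="satterthwaite")
    t = fit.anova_table.set_index("term")
    cond = t.loc["C(condition, Sum)"]
    tp = t.loc["C(timepoint, Sum)"]
    inter = t.loc["C(condition, Sum):C(timepoint, Sum)"]
    assert cond["F"] == pytest.approx(1.0096, rel=0.02)
    assert cond["df2"] == pytest.approx(11.0, rel=0.03)
    assert cond["p"] == pytest.approx(0.33659, abs=0.005)
    assert tp["F"] == pytest.approx(2.5930, rel=0.02)
    assert tp["df2"] == pytest.approx(66.0, rel=0.03)
    assert tp["p"] == pytest.approx(0.05995, abs=0.005)
    assert inter["F"] == pytest.approx(2.0153, rel=0.02)
    assert inter["df2"] == pytest.approx(66.0, rel=0.03)
    assert inter["p"] == pytest.approx(0.12029, abs=0.005)


def test_lmm_between_within_df_convention():
    fit = fit_trial_lmm(_lmm_fixture(), dv="y", random_structure="condition",
                        df_method="between-within")
    assert (fit.anova_table["df2"] == 11).all()  # participants - 1
    assert fit.emmeans is not None and len(fit.emmeans) == 2


def test_lmm_recovers_injected_condition_effect():
    """A flat 1.3x verum effect appears in the squared marginal means."""
    from tusmep.emg import transform_amplitudes
    from tusmep.synthetic import EmgGenConfig, generate_emg_cohort

    effect = {t: 1.3 for t in ("Baseline", "T5", "T30", "T60")}
    cfg = EmgGenConfig(muscles=("FDI",), muscle_scale=(1.0,),
                       condition_effect=effect, condition_log_sd=0.05, seed=21)
    df = generate_emg_cohort(cfg, waveforms=False).trials
    sub = df.loc[df["pulse_type"] == "single"].copy()
    sub["amp_sqrt"] = transform_amplitudes(sub["amp_true"])
    fit = fit_trial_lmm(sub, random_structure="condition+cell",
                        df_method="between-within")
    emm = fit.emmeans.set_index("condition")["emmean"]
    ratio = (emm["verum"] / emm["sham"]) ** 2
    assert ratio == pytest.approx(1.3, rel=0.10)


def test_lmm_requires_multiple_participants():
    df = _lmm_fixture()
    with pytest.raises(ValueError):
        fit_trial_lmm(df.loc[df["participant"] == 0], dv="y")


# ------------------------------------------------------------ rm-ANOVA

def _rm_oracle(wide: np.ndarray):
    """Brute-force sums of squares for a two-way fully-within design.

    ``wide`` has shape (subjects, A levels, B levels).  Returns F statistics
    for A, B and AxB.
    """
    n, a, b = wide.shape
    grand = wide.mean()
    mA = wide.mean(axis=(0, 2))
    mB = wide.mean(axis=(0, 1))
    mS = wide.mean(axis=(1, 2))
    mAB = wide.mean(axis=0)
    mSA = wide.mean(axis=2)
    mSB = wide.mean(axis=1)
    ssA = n * b * ((mA - grand) ** 2).sum()
    ssB = n * a * ((mB - grand) ** 2).sum()
    ssAB = n * ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    ssSA = b * ((mSA - mS[:, None] - mA[None, :] + grand) ** 2).sum()
    ssSB = a * ((mSB - mS[:, None] - mB[None, :] + grand) ** 2).sum()
    ssE = ((wide - mAB[None] - mSA[:, :, None] - mSB[:, None, :]
            + mA[None, :, None] + mB[None, None, :] + mS[:, None, None]
            - grand) ** 2).sum()
    fA = (ssA / (a - 1)) / (ssSA / ((n - 1) * (a - 1)))
    fB = (ssB / (b - 1)) / (ssSB / ((n - 1) * (b - 1)))
    fAB = (ssAB / ((a - 1) * (b - 1))) / (ssE / ((n - 1) * (a - 1) * (b - 1)))
    return fA, fB, fAB


def test_rm_anova_against_brute_force_oracle():
    rng = np.random.default_rng(3)
    n, conds, tps = 8, ["sham", "verum"], ["Baseline", "T5", "T30", "T60"]
    rows = []
    cube = np.empty((n, 2, 4))
    for s in range(n):
        for i, c in enumerate(conds):
            for j, t in enumerate(tps):
                y = rng.normal(1.0 + 0.1 * i + 0.05 * j, 0.3)
                cube[s, i, j] = y
                rows.append({"participant": s, "condition": c,
                             "timepoint": t, "mean_single": y})
    fit = rm_anova(pd.DataFrame(rows))
    fA, fB, fAB = _rm_oracle(cube)
    t = fit.anova_table.set_index("term")
    assert t.loc["condition", "F"] == pytest.approx(fA, rel=1e-6)
    assert t.loc["timepoint", "F"] == pytest.approx(fB, rel=1e-6)
    assert t.loc["condition * timepoint", "F"] == pytest.approx(fAB, rel=1e-6)
    # GG-corrected dfs present and shrunken
    assert (t["df1_gg"] <= t["df1"] + 1e-9).all()
    assert t.loc["condition", "eps"] == pytest.approx(1.0)


def test_rm_anova_all_equal_cells():
    rows = [{"participant": s, "condition": c, "timepoint": t,
             "mean_single": 1.0}
            for s in range(5) for c in ["a", "b"] for t in ["x", "y"]]
    fit = rm_anova(pd.DataFrame(rows))
    assert np.allclose(np.nan_to_num(fit.anova_table["F"]), 0.0)


def test_rm_anova_rejects_missing_cells():
    rows = [{"participant": s, "condition": c, "timepoint": t,
             "mean_single": 1.0}
            for s in range(5) for c in ["a", "b"] for t in ["x", "y"]]
    with pytest.raises(ValueError):
        rm_anova(pd.DataFrame(rows[:-1]))


# ------------------------------------------------------------ power

def test_power_null_effect_equals_alpha():
    spec = PowerSpec(eta_p2=0.0, family="between")
    assert rm_anova_power(spec, 10) == pytest.approx(0.05, abs=1e-6)


def test_power_monotone_in_n_and_f():
    spec = PowerSpec(eta_p2=0.2, family="between")
    powers = [rm_anova_power(spec, n) for n in range(4, 60, 2)]
    assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))
    stronger = PowerSpec(eta_p2=0.4, family="between")
    assert rm_anova_power(stronger, 20) > rm_anova_power(spec, 20)


def test_power_monotone_in_correlation_per_family():
    lo = PowerSpec(eta_p2=0.2, rho_rm=0.3, family="within")
    hi = PowerSpec(eta_p2=0.2, rho_rm=0.7, family="within")
    assert rm_anova_power(hi, 12) > rm_anova_power(lo, 12)
    lo_b = PowerSpec(eta_p2=0.2, rho_rm=0.3, family="between")
    hi_b = PowerSpec(eta_p2=0.2, rho_rm=0.7, family="between")
    assert rm_anova_power(hi_b, 12) < rm_anova_power(lo_b, 12)


def test_required_sample_size_definition():
    spec = PowerSpec(eta_p2=0.3, family="between")
    n = required_sample_size(spec)
    assert rm_anova_power(spec, n) >= 0.8
    assert rm_anova_power(spec, n - spec.n_groups) < 0.8 \
        or n == 2 * spec.n_groups
    tiny = PowerSpec(eta_p2=0.0099, family="between")  # f ~ 0.1
    assert required_sample_size(tiny) >= 100


# ------------------------------------------------------------ regressions

def test_overlap_regression():
    df = pd.DataFrame({
        "timepoint": ["T5"] * 5,
        "overlap_pct": [0.0, 10.0, 20.0, 30.0, 40.0],
        "baseline_ratio": [1.0, 1.0, 1.0, 1.0, 1.0],
    })
    res = overlap_regression(df)
    assert res.iloc[0]["slope"] == pytest.approx(0.0, abs=1e-12)
    line = df.assign(baseline_ratio=2.0 * df["overlap_pct"])
    res = overlap_regression(line)
    assert res.iloc[0]["slope"] == pytest.approx(2.0)
    assert res.iloc[0]["p"] < 1e-9
    with pytest.raises(ValueError):
        overlap_regression(df.assign(overlap_pct=5.0))


def test_accuracy_subgroup():
    focus = pd.DataFrame({"participant": [0, 1, 2],
                          "overlap_pct": [10.0, 25.0, 30.0],
                          "roi_peak_isppa": [0.5, 1.0, 1.2]})
    out = accuracy_subgroup(focus, threshold=20.0)
    assert out["n_above_threshold"] == 2
    assert out["roi_peak_mean"] == pytest.approx(1.1)
    empty = accuracy_subgroup(focus.assign(overlap_pct=0.0), threshold=20.0)
    assert empty["n_above_threshold"] == 0 and empty["roi_peak_mean"] is None
    full = accuracy_subgroup(focus, threshold=0.0)
    assert full["n_above_threshold"] == 3
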