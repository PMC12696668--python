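import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from tusmep.emg import (clean_trials, compute_peak_to_peak,
                        compute_pre_rms, flag_noise, flag_outliers_grubbs,
                        flag_precontraction, grubbs_critical_value,
                        normalize_to_baseline, summarize_blocks,
                        transform_amplitudes)


# ---------------------------------------------------------------- measures

def test_peak_to_peak_basic():
    assert compute_peak_to_peak(np.zeros(100), (10, 90)) == 0.0
    t = np.linspace(0, 1, 1000, endpoint=False)
    wave = 0.5 * np.sin(2 * np.pi * t)
    assert compute_peak_to_peak(wave, (0, 1000)) == pytest.approx(1.0, rel=1e-4)
    with pytest.raises(ValueError):
        compute_peak_to_peak(wave, (500, 500))


@settings(max_examples=30, deadline=None)
@given(st.floats(min_value=-10, max_value=10))
def test_peak_to_peak_offset_and_sign_invariance(offset):
    rng = np.random.default_rng(0)
    wave = rng.normal(size=200)
    ref = compute_peak_to_peak(wave, (0, 200))
    assert compute_peak_to_peak(wave + offset, (0, 200)) == pytest.approx(ref)
    assert compute_peak_to_peak(-wave, (0, 200)) == pytest.approx(ref)


def test_pre_rms():
    # constant segment: RMS equals the constant
    wf = np.full(500, 0.045)
    assert compute_pre_rms(wf, 500, 5000.0) == pytest.approx(0.045)
    # 100 ms at 20 Hz is two samples: {3, 4} -> sqrt(12.5)
    assert compute_pre_rms(np.array([3.0, 4.0, 9.9]), 2, 20.0) == pytest.approx(
        np.sqrt(12.5))
    assert compute_pre_rms(np.zeros(600), 600, 5000.0) == 0.0
    with pytest.raises(ValueError):
        compute_pre_rms(np.zeros(600), 400, 5000.0)  # only 80 ms available


# ---------------------------------------------------------------- grubbs

def test_grubbs_flags_single_outlier():
    x = np.array([1.0, 1.02, 0.98, 1.01, 0.99, 5.0])
    flags = flag_outliers_grubbs(x, alpha=0.05)
    assert flags.tolist() == [False] * 5 + [True]


def test_grubbs_no_outliers_when_identical():
    assert not flag_outliers_grubbs(np.full(10, 1.5)).any()
    with pytest.raises(ValueError):
        flag_outliers_grubbs(np.array([1.0, 2.0]))


def test_grubbs_iterates_over_multiple_outliers():
    x = np.concatenate([np.full(20, 1.0) + np.linspace(-0.02, 0.02, 20),
                        [6.0, 9.0]])
    flags = flag_outliers_grubbs(x)
    assert flags[-2:].all() and not flags[:-2].any()


def test_grubbs_critical_value_against_simulation():
    """The t-based critical value matches the null quantile of the G statistic.

    Brute-force oracle: simulate max|x - mean|/sd under normality and compare
    its (1 - alpha) quantile (with the Bonferroni-style two-sided adjustment
    the closed form encodes) to the formula.
    """
    rng = np.random.default_rng(42)
    n, alpha = 10, 0.05
    sims = rng.standard_normal((40_000, n))
    g = (np.abs(sims - sims.mean(axis=1, keepdims=True)).max(axis=1)
         / sims.std(axis=1, ddof=1))
    crit = grubbs_critical_value(n, alpha)
    observed_rate = (g > crit).mean()
    # one-shot two-sided test: rejection rate close to (slightly below) alpha
    assert 0.02 <= observed_rate <= 0.06


# ---------------------------------------------------------------- rules

def test_precontraction_rule():
    assert not flag_precontraction(np.full(25, 0.01)).any()  # sd = 0
    block = np.array([0.010] * 24 + [0.100])
    flags = flag_precontraction(block)
    assert flags.tolist() == [False] * 24 + [True]
    with pytest.raises(ValueError):
        flag_precontraction(np.array([0.01, 0.02]))


def test_precontraction_includes_candidate_in_stats():
    # hand evaluation: mean = 0.0136, sd(ddof=1) = 0.018; threshold = 0.0496
    block = np.array([0.010] * 24 + [0.100])
    thresh = block.mean() + 2 * block.std(ddof=1)
    assert (block > thresh).sum() == 1


@pytest.mark.parametrize("pre_rms,mep_pp,pre_pp,expected", [
    (0.01, 0.0, 10.0, False),   # below inspection threshold: never flagged
    (0.10, 0.05, 0.30, True),   # SNR 0.17 < 2
    (0.10, 2.00, 0.30, False),  # SNR 6.7 >= 2
])
def test_noise_rule(pre_rms, mep_pp, pre_pp, expected):
    got = flag_noise(np.array([pre_rms]), np.array([mep_pp]),
                     np.array([pre_pp]))
    assert got.tolist() == [expected]


# ---------------------------------------------------------------- pipeline

def test_cleaning_flags_are_disjoint_and_union(fast_cohort):
    cleaned = clean_trials(fast_cohort.trials)
    overlap = (cleaned["flag_outlier"] & cleaned["flag_precontraction"]) | \
        (cleaned["flag_outlier"] & cleaned["flag_noise"]) | \
        (cleaned["flag_precontraction"] & cleaned["flag_noise"])
    assert not overlap.any()
    union = (cleaned["flag_outlier"] | cleaned["flag_precontraction"]
             | cleaned["flag_noise"])
    assert (cleaned["excluded"] == union).all()


def test_cleaning_is_idempotent(fast_cohort):
    once = clean_trials(fast_cohort.trials)
    twice = clean_trials(once)
    for col in ("flag_outlier", "flag_precontraction", "flag_noise",
                "excluded"):
        assert (once[col] == twice[col]).all()


def test_grubbs_fixed_point_after_dropping_outliers(fast_cohort):
    cleaned = clean_trials(fast_cohort.trials)
    kept = cleaned.loc[~cleaned["flag_outlier"]].drop(
        columns=["flag_outlier", "flag_precontraction", "flag_noise",
                 "excluded"])
    again = clean_trials(kept)
    assert not again["flag_outlier"].any()


def test_ground_truth_recovery(fast_cohort):
    df = fast_cohort.trials
    cleaned = clean_trials(df)
    gt = df["is_precontraction_gt"]
    clean_mask = ~(gt | df["is_noise_gt"] | df["is_outlier_gt"])
    sens = (cleaned["flag_precontraction"] & gt).sum() / gt.sum()
    false_rate = ((cleaned["flag_precontraction"] & clean_mask).sum()
                  / clean_mask.sum())
    assert sens >= 0.9
    assert false_rate <= 0.05
    out_sens = ((cleaned["flag_outlier"] & df["is_outlier_gt"]).sum()
                / df["is_outlier_gt"].sum())
    assert out_sens >= 0.9
    # broadband-noise trials are caught by some rule (attribution may fall to
    # the pre-contraction rule, which fires first on a contaminated pre-window)
    noise_caught = ((cleaned["excluded"] & df["is_noise_gt"]).sum()
                    / df["is_noise_gt"].sum())
    assert noise_caught >= 0.9


# ---------------------------------------------------------------- summaries

def _toy_trials():
    rows = []
    amps = {"single": 1.0, "TS": 1.0, "SICI": 0.45, "ICF": 1.3}
    for tp, scale in (("Baseline", 1.0), ("T5", 1.5)):
        for pt, amp in amps.items():
            for i in range(5):
                rows.append({
                    "participant": 0, "condition": "sham", "timepoint": tp,
                    "muscle": "FDI", "pulse_type": pt, "acq_block":
                        "single" if pt == "single" else "paired",
                    "mep_pp": amp * scale, "pre_rms": 0.008, "pre_pp": 0.05,
                    "flag_outlier": False, "flag_precontraction": False,
                    "flag_noise": False, "excluded": False,
                })
    return pd.DataFrame(rows)


def test_summarize_blocks_ratios():
    out = summarize_blocks(_toy_trials())
    base = out.loc[out["timepoint"] == "Baseline"].iloc[0]
    assert base["mean_single"] == pytest.approx(1.0)
    assert base["sici_ratio"] == pytest.approx(0.45)
    assert base["icf_ratio"] == pytest.approx(1.3)


def test_summarize_blocks_empty_measure_is_nan():
    df = _toy_trials()
    df.loc[df["pulse_type"] == "ICF", "excluded"] = True
    out = summarize_blocks(df)
    assert out["mean_ICF"].isna().all()
    assert out["icf_ratio"].isna().all()


def test_normalize_to_baseline():
    out = summarize_blocks(_toy_trials())
    ratios = normalize_to_baseline(out)
    t5 = ratios.loc[ratios["timepoint"] == "T5"].iloc[0]
    assert t5["mean_single_baseline_ratio"] == pytest.approx(1.5)
    assert t5["sici_ratio_baseline_ratio"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_to_baseline(out.loc[out["timepoint"] != "Baseline"])


def test_transform_amplitudes():
    got = transform_amplitudes([0.0, 1.0, 2.25])
    assert got.tolist() == [0.0, 1.0, 1.5]
    with pytest.raises(ValueError):
        transform_amplitudes([-1.0])


def test_measured_amplitudes_match_generated_ground_truth(small_cohort):
    """Waveform synthesis and peak-to-peak measurement agree."""
    df = small_cohort.trials
    clean = df.loc[~(df["is_outlier_gt"] | df["is_precontraction_gt"]
                     | df["is_noise_gt"])]
    rel = (clean["mep_pp"] - clean["amp_true"]) / clean["amp_true"]
    assert rel.abs().median() < 0.05
    assert (df["mep_pp"] >= 0).all()
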