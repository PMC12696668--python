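"""Trial-level MEP preprocessing: measurement, exclusion, summarisation.

The cleaning pipeline mirrors standard single/paired-pulse TMS practice:

1. per-block iterative two-sided Grubbs test on raw peak-to-peak amplitudes;
2. pre-contraction flag — pre-stimulus RMS exceeding the block mean by two
   standard deviations (statistics computed once over all trials in the
   block, candidate included);
3. noise flag — a deterministic surrogate for manual inspection: pre-RMS
   above a liberal threshold (0.045 mV) *and* a response-to-background
   peak-to-peak ratio below ``noise_snr_min``.

Flags are attributed disjointly in that order; a trial is excluded if any
rule fired for the muscle channel in question.  Paired-pulse amplitudes are
summarised as a ratio to the mean test-stimulus (TS) amplitude, and post
timepoints as a ratio to the baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CleaningRules",
    "compute_peak_to_peak",
    "compute_pre_rms",
    "response_window",
    "grubbs_critical_value",
    "flag_outliers_grubbs",
    "flag_precontraction",
    "flag_noise",
    "measure_cohort",
    "clean_trials",
    "exclusion_summary",
    "summarize_blocks",
    "normalize_to_baseline",
    "transform_amplitudes",
]

BLOCK_KEY = ["participant", "condition", "timepoint", "muscle"]


@dataclass(frozen=True)
class CleaningRules:
    grubbs_alpha: float = 0.05
    precontraction_k: float = 2.0  # SD multiplier on the block pre-RMS
    pre_window_ms: float = 100.0
    rms_inspect_threshold: float = 0.045  # mV
    noise_snr_min: float = 2.0
    response_start_ms: float = 15.0  # post-stimulus MEP search window
    response_end_ms: float = 60.0

    def __post_init__(self) -> None:
        for name in ("grubbs_alpha", "precontraction_k", "pre_window_ms",
                     "rms_inspect_threshold", "noise_snr_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.response_start_ms < self.response_end_ms:
            raise ValueError("response window must be non-empty")


def response_window(
    stimulus_sample: int, sampling_rate: float,
    start_ms: float = 15.0, end_ms: float = 60.0,
) -> tuple[int, int]:
    """Sample window [start, end) for the MEP search, post-stimulus."""
    start = stimulus_sample + int(round(start_ms * sampling_rate / 1000.0))
    end = stimulus_sample + int(round(end_ms * sampling_rate / 1000.0))
    return start, end


def compute_peak_to_peak(waveform: np.ndarray, window: tuple[int, int]) -> float:
    """max - min of the waveform restricted to [window[0], window[1])."""
    start, end = window
    seg = np.asarray(waveform, dtype=float)[start:end]
    if seg.size == 0:
        raise ValueError("empty response window")
    return float(seg.max() - seg.min())


def compute_pre_rms(
    waveform: np.ndarray, stimulus_sample: int, sampling_rate: float,
    pre_window_ms: float = 100.0,
) -> float:
    """RMS over the pre_window_ms window ending at the stimulus (exclusive)."""
    n = int(round(pre_window_ms * sampling_rate / 1000.0))
    if stimulus_sample < n:
        raise ValueError("insufficient pre-stimulus samples")
    seg = np.asarray(waveform, dtype=float)[stimulus_sample - n:stimulus_sample]
    return float(np.sqrt(np.mean(seg ** 2)))


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def flag_outliers_grubbs(amplitudes: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; True where a value was rejected.

    The most extreme value is tested against the critical value for the
    current sample size, removed if significant, and the test repeated until
    no rejection or fewer than three values remain.  A zero-variance sample
    yields no outliers.
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.ndim != 1:
        raise ValueError("amplitudes must be 1-D")
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 trials")
    flags = np.zeros(x.size, dtype=bool)
    active = np.ones(x.size, dtype=bool)
    while active.sum() >= 3:
        cur = x[active]
        sd = cur.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(cur - cur.mean())
        g = dev.max() / sd
        if g <= grubbs_critical_value(cur.size, alpha):
            break
        # reject the first most-extreme value (deterministic tie-break)
        local = int(np.argmax(dev))
        global_idx = np.flatnonzero(active)[local]
        flags[global_idx] = True
        active[global_idx] = False
    return flags


def flag_precontraction(pre_rms: np.ndarray, k: float = 2.0) -> np.ndarray:
    """True where pre-RMS exceeds the block mean by k standard deviations.

    The mean and SD are computed once over all trials in the block,
    candidates included (non-iterative); SD uses the n-1 denominator.
    """
    x = np.asarray(pre_rms, dtype=float)
    if x.size < 3:
        raise ValueError("pre-contraction rule needs at least 3 trials")
    sd = x.std(ddof=1)
    return x > x.mean() + k * sd


def flag_noise(
    pre_rms: np.ndarray, mep_pp: np.ndarray, pre_pp: np.ndarray,
    rules: CleaningRules = CleaningRules(),
) -> np.ndarray:
    """Deterministic stand-in for manual inspection of noisy trials.

    A trial is flagged iff its pre-RMS exceeds the liberal inspection
    threshold and the MEP peak-to-peak is less than ``noise_snr_min`` times
    the pre-window peak-to-peak, i.e. the response does not clear the
    background well enough to be quantified.
    """
    pre_rms = np.asarray(pre_rms, dtype=float)
    mep_pp = np.asarray(mep_pp, dtype=float)
    pre_pp = np.asarray(pre_pp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(pre_pp > 0, mep_pp / pre_pp, np.inf)
    return (pre_rms > rules.rms_inspect_threshold) & (snr < rules.noise_snr_min)


def measure_cohort(cohort) -> pd.DataFrame:
    """Derive mep_pp, pre_rms and pre_pp from a cohort's waveforms."""
    if cohort.waveforms is None:
        raise ValueError("cohort carries no waveforms")
    rules = CleaningRules()
    sr = cohort.sampling_rate
    stim = cohort.stimulus_sample
    win = response_window(stim, sr, rules.response_start_ms, rules.response_end_ms)
    wf = cohort.waveforms
    seg = wf[:, win[0]:win[1]].astype(float)
    mep_pp = seg.max(axis=1) - seg.min(axis=1)
    n_pre = int(round(rules.pre_window_ms * sr / 1000.0))
    pre = wf[:, stim - n_pre:stim].astype(float)
    pre_rms = np.sqrt(np.mean(pre ** 2, axis=1))
    pre_pp = pre.max(axis=1) - pre.min(axis=1)
    df = cohort.trials.copy()
    df["mep_pp"] = mep_pp
    df["pre_rms"] = pre_rms
    df["pre_pp"] = pre_pp
    return df


def clean_trials(
    trials: pd.DataFrame, rules: CleaningRules = CleaningRules()
) -> pd.DataFrame:
    """Apply the three exclusion rules; returns the table with flag columns.

    Grubbs runs per participant x condition x timepoint x muscle x pulse
    type (amplitudes are only comparable within a measure); the
    pre-contraction rule runs per acquisition block and muscle channel
    (single-pulse vs interleaved paired-pulse block).  Flags are disjoint:
    outlier beats pre-contraction beats noise.  Rows are kept, never
    dropped, so re-running the cleaner reproduces identical flags.
    """
    df = trials.copy()
    df["flag_outlier"] = False
    df["flag_precontraction"] = False
    df["flag_noise"] = False

    for _, idx in df.groupby(BLOCK_KEY + ["pulse_type"], sort=False).groups.items():
        amps = df.loc[idx, "mep_pp"].to_numpy()
        df.loc[idx, "flag_outlier"] = flag_outliers_grubbs(amps, rules.grubbs_alpha)

    pre_key = BLOCK_KEY + (["acq_block"] if "acq_block" in df.columns else [])
    for _, idx in df.groupby(pre_key, sort=False).groups.items():
        pr = df.loc[idx, "pre_rms"].to_numpy()
        df.loc[idx, "flag_precontraction"] = flag_precontraction(
            pr, rules.precontraction_k)

    noise = flag_noise(df["pre_rms"], df["mep_pp"],
                       df.get("pre_pp", pd.Series(0.0, index=df.index)), rules)
    df["flag_noise"] = noise

    # disjoint attribution: Grubbs -> pre-contraction -> noise
    df["flag_precontraction"] &= ~df["flag_outlier"]
    df["flag_noise"] &= ~(df["flag_outlier"] | df["flag_precontraction"])
    df["excluded"] = (df["flag_outlier"] | df["flag_precontraction"]
                      | df["flag_noise"])
    return df


def exclusion_summary(cleaned: pd.DataFrame) -> dict:
    """Aggregate exclusion percentages per rule, across all trials."""
    n = len(cleaned)
    return {
        "n_trials": int(n),
        "pct_outlier": float(100.0 * cleaned["flag_outlier"].mean()),
        "pct_precontraction": float(100.0 * cleaned["flag_precontraction"].mean()),
        "pct_noise": float(100.0 * cleaned["flag_noise"].mean()),
        "pct_excluded": float(100.0 * cleaned["excluded"].mean()),
    }


def summarize_blocks(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Per-block means over unexcluded trials and paired-pulse ratios.

    One row per participant x condition x timepoint x muscle with the mean
    amplitude of each measure, SICI/ICF expressed as a ratio to the mean TS,
    and exclusion counts.  Empty measures yield NaN (explicit missing), not
    zero.
    """
    keep = cleaned.loc[~cleaned["excluded"]]
    means = (keep.pivot_table(index=BLOCK_KEY, columns="pulse_type",
                              values="mep_pp", aggfunc="mean")
             .rename(columns={"single": "mean_single", "TS": "mean_TS",
                              "SICI": "mean_SICI", "ICF": "mean_ICF"}))
    counts = cleaned.groupby(BLOCK_KEY).agg(
        n_total=("mep_pp", "size"),
        n_outlier=("flag_outlier", "sum"),
        n_precontraction=("flag_precontraction", "sum"),
        n_noise=("flag_noise", "sum"),
        n_excluded=("excluded", "sum"),
    )
    out = counts.join(means).reset_index()
    for col in ("mean_single", "mean_TS", "mean_SICI", "mean_ICF"):
        if col not in out.columns:
            out[col] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        out["sici_ratio"] = out["mean_SICI"] / out["mean_TS"]
        out["icf_ratio"] = out["mean_ICF"] / out["mean_TS"]
    return out


def normalize_to_baseline(
    summaries: pd.DataFrame,
    value_cols: tuple[str, ...] = ("mean_single", "sici_ratio", "icf_ratio"),
    baseline_label: str = "Baseline",
) -> pd.DataFrame:
    """Express post-timepoint values as a ratio to the baseline mean.

    Ratios are computed within participant x condition x muscle; a missing
    baseline for any key raises.
    """
    key = ["participant", "condition", "muscle"]
    base = summaries.loc[summaries["timepoint"] == baseline_label,
                         key + list(value_cols)]
    if base.empty:
        raise ValueError("no baseline blocks found")
    post = summaries.loc[summaries["timepoint"] != baseline_label].copy()
    merged = post.merge(base, on=key, how="left", suffixes=("", "_baseline"))
    missing = merged[[f"{c}_baseline" for c in value_cols]].isna().all(axis=1)
    if missing.any():
        bad = merged.loc[missing, key].drop_duplicates()
        raise ValueError(f"missing baseline for keys:\n{bad}")
    for c in value_cols:
        merged[f"{c}_baseline_ratio"] = merged[c] / merged[f"{c}_baseline"]
    keep = key + ["timepoint"] + [f"{c}_baseline_ratio" for c in value_cols]
    return merged[keep]


def transform_amplitudes(amplitudes) -> np.ndarray:
    """Square-root variance-stabilising transform for right-skewed MEPs."""
    x = np.asarray(amplitudes, dtype=float)
    if np.any(x < 0):
        raise ValueError("amplitudes must be non-negative")
    return np.sqrt(x)
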