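"""End-to-end orchestration: synthetic cohort -> cleaning -> statistics ->
dosimetry -> targeting metrics -> machine-readable replication report.

The report is a schema-versioned JSON document mirroring the result
sections of a TUS-TMS replication study: exclusion percentages per rule,
baseline paired tests, the trial-level LMM and rm-ANOVA tables, dose
estimates, per-participant focus reports, group targeting statistics, the
accuracy subgroup and the overlap-vs-MEP regression, plus a provenance
block (seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosimetry import SonicationProtocol, estimate_doses
from .emg import (CleaningRules, clean_trials, exclusion_summary,
                  normalize_to_baseline, summarize_blocks,
                  transform_amplitudes)
from .focus import compute_focus_report, group_axis_tests, group_focus_map
from .inference import (FitResult, accuracy_subgroup, baseline_paired_tests,
                        fit_trial_lmm, overlap_regression, rm_anova)
from .synthetic import (EmgGenConfig, FieldGenConfig, generate_cohort_fields,
                        generate_emg_cohort, original_study_preset)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_lmm_pvalues",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    preset: str = "null"  # 'null' or 'original-study'
    emg: dict = field(default_factory=dict)  # EmgGenConfig overrides
    fields: dict = field(default_factory=dict)  # FieldGenConfig overrides
    cleaning: dict = field(default_factory=dict)  # CleaningRules overrides
    synthesize_waveforms: bool = False
    lmm_df_method: str = "satterthwaite"
    lmm_random_structure: str = "auto"
    subgroup_threshold_pct: float = 20.0
    primary_muscle: str = "FDI"
    out_dir: str | None = None

    def emg_config(self) -> EmgGenConfig:
        overrides = dict(self.emg)
        overrides.setdefault("seed", self.seed)
        if self.preset == "original-study":
            return original_study_preset(**overrides)
        if self.preset != "null":
            raise ValueError(f"unknown preset {self.preset!r}")
        return EmgGenConfig(**overrides)

    def field_config(self) -> FieldGenConfig:
        overrides = dict(self.fields)
        overrides.setdefault("seed", self.seed + 1)
        for key in ("grid_shape", "focus_fwhm", "placement_bias",
                    "placement_sd", "target_point"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return FieldGenConfig(**overrides)

    def cleaning_rules(self) -> CleaningRules:
        return CleaningRules(**self.cleaning)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _table(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def _fit_section(fit: FitResult) -> dict:
    out = {"anova": _table(fit.anova_table), "df_method": fit.df_method,
           "random_structure": fit.random_structure,
           "converged": fit.converged, "fallback_used": fit.fallback_used}
    if fit.emmeans is not None:
        out["emmeans"] = _table(fit.emmeans)
    return out


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage on a freshly generated synthetic cohort."""
    cfg = config or PipelineConfig()
    emg_cfg = cfg.emg_config()
    rules = cfg.cleaning_rules()
    muscle = cfg.primary_muscle
    if muscle not in emg_cfg.muscles:
        raise ValueError(f"primary muscle {muscle!r} not generated")

    # --- EMG branch -------------------------------------------------------
    cohort = generate_emg_cohort(emg_cfg, waveforms=cfg.synthesize_waveforms)
    cleaned = clean_trials(cohort.trials, rules)
    exclusions = exclusion_summary(cleaned)
    summaries = summarize_blocks(cleaned)

    fdi = summaries.loc[summaries["muscle"] == muscle]
    base = fdi.loc[fdi["timepoint"] == "Baseline"]
    long = pd.concat([
        base.assign(measure="mep_amplitude", value=base["mean_single"]),
        base.assign(measure="sici", value=base["sici_ratio"]),
        base.assign(measure="icf", value=base["icf_ratio"]),
    ])[["participant", "condition", "measure", "value"]]
    baseline_tests = baseline_paired_tests(long)

    ratios = normalize_to_baseline(summaries)
    fdi_ratios = (ratios.loc[ratios["muscle"] == muscle,
                             ["participant", "condition", "timepoint",
                              "mean_single_baseline_ratio"]]
                  .rename(columns={"mean_single_baseline_ratio":
                                   "baseline_ratio"}))

    lmm_trials = cleaned.loc[(cleaned["muscle"] == muscle)
                             & (cleaned["pulse_type"] == "single")
                             & ~cleaned["excluded"]].copy()
    lmm_trials["amp_sqrt"] = transform_amplitudes(lmm_trials["mep_pp"])
    lmm = fit_trial_lmm(lmm_trials, dv="amp_sqrt",
                        df_method=cfg.lmm_df_method,
                        random_structure=cfg.lmm_random_structure)

    anova = rm_anova(fdi, dv="mean_single")

    # --- acoustic branch --------------------------------------------------
    field_cfg = cfg.field_config()
    fields = generate_cohort_fields(field_cfg, emg_cfg.n_participants)
    from .focus import intensity_volume_from_pressure

    reports = []
    shifts = []
    focus_masks = []
    for pressure, head in fields:
        intensity = intensity_volume_from_pressure(pressure)
        rep = compute_focus_report(intensity, head)
        reports.append(rep)
        shifts.append(rep.axis_shift)
        focus_masks.append(rep.focus_mask)
    shifts = np.asarray(shifts)
    axis_tests = group_axis_tests(shifts)
    count_map = group_focus_map(focus_masks)

    focus_df = pd.DataFrame({
        "participant": np.arange(len(reports)),
        "overlap_pct": [r.overlap_pct for r in reports],
        "roi_peak_isppa": [r.roi_peak_isppa for r in reports],
        "peak_isppa": [r.peak_isppa for r in reports],
        "dist_omega": [r.dist_omega for r in reports],
        "dist_lip": [r.dist_lip for r in reports],
    })

    # verum-session MEP change vs targeting accuracy
    verum_ratios = fdi_ratios.loc[fdi_ratios["condition"] == "verum"]
    reg_data = verum_ratios.merge(focus_df[["participant", "overlap_pct"]],
                                  on="participant")
    regression = overlap_regression(reg_data)
    subgroup = accuracy_subgroup(focus_df, verum_ratios,
                                 cfg.subgroup_threshold_pct)

    # --- dosimetry --------------------------------------------------------
    doses = estimate_doses(
        protocol=SonicationProtocol(),
        isppa_tc_simulated=float(focus_df["peak_isppa"].mean()))

    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {"seed": cfg.seed, "config_hash": cfg.hash(),
                       "package_version": __version__,
                       "preset": cfg.preset},
        "exclusions": exclusions,
        "baseline_tests": _table(baseline_tests),
        "lmm": _fit_section(lmm),
        "rm_anova": _fit_section(anova),
        "dose_estimates": doses.as_dict(),
        "focus_reports": [r.as_dict() for r in reports],
        "targeting": {
            "dist_omega_mean": float(focus_df["dist_omega"].mean()),
            "dist_omega_sd": float(focus_df["dist_omega"].std(ddof=1)),
            "dist_lip_mean": float(focus_df["dist_lip"].mean()),
            "peak_isppa_mean": float(focus_df["peak_isppa"].mean()),
            "peak_isppa_sd": float(focus_df["peak_isppa"].std(ddof=1)),
            "axis_tests": axis_tests,
            "focus_map_max_count": int(count_map.values.max()),
        },
        "subgroup": subgroup,
        "overlap_regression": _table(regression),
    }

    if cfg.out_dir is not None:
        from . import io as tio

        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_json_report(report, out / "replication_report.json")
        tio.write_trials(cleaned, out / "trials.csv")
        tio.write_volume(count_map, out / "focus_count_map.nii")
        if cohort.waveforms is not None:
            tio.write_waveforms(cohort.waveforms,
                                cohort.trials["trial_id"].to_numpy(),
                                cohort.sampling_rate, cohort.stimulus_sample,
                                out / "waveforms.h5")
    return report


def simulate_lmm_pvalues(
    n_reps: int,
    seed: int,
    preset: str = "null",
    n_participants: int = 15,
    rules: CleaningRules | None = None,
) -> pd.DataFrame:
    """Monte-Carlo p-values of the generator -> cleaning -> LMM chain.

    Each replicate draws a fresh single-muscle cohort (amplitude fast
    path), applies the full exclusion pipeline and fits the trial-level
    model with the condition random slope and between-within dfs (the
    package's simulation-study configuration).  Returns one row per
    replicate with the p-value of each fixed-effect term.
    """
    rules = rules or CleaningRules()
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        sub_seed = int(master.integers(0, 2**31))
        overrides = dict(muscles=("FDI",), muscle_scale=(1.0,),
                         n_participants=n_participants, seed=sub_seed)
        cfg = (original_study_preset(**overrides) if preset == "original-study"
               else EmgGenConfig(**overrides))
        cohort = generate_emg_cohort(cfg, waveforms=False)
        cleaned = clean_trials(cohort.trials, rules)
        sub = cleaned.loc[(cleaned["pulse_type"] == "single")
                          & ~cleaned["excluded"]].copy()
        sub["amp_sqrt"] = transform_amplitudes(sub["mep_pp"])
        fit = fit_trial_lmm(sub, dv="amp_sqrt", df_method="between-within",
                            random_structure="condition+cell")
        row = {"rep": rep, "seed": sub_seed}
        for _, r in fit.anova_table.iterrows():
            term = r["term"]
            if "condition" in term and "timepoint" in term:
                row["p_interaction"] = r["p"]
            elif "condition" in term:
                row["p_condition"] = r["p"]
            elif "timepoint" in term:
                row["p_timepoint"] = r["p"]
        rows.append(row)
    return pd.DataFrame(rows)
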