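"""End-to-end study orchestration.

``run_study`` drives a full synthetic (or file-based) study: it builds a
two-group pre/post cohort of pulmonary scalars, per-subject FMD traces
and RR series, runs the vascular / HRV / reliability / stats stages, and
writes a report bundle of tidy CSV tables: a reliability table, group
tables with percent changes and test p-values, an FMD summary, and
reactive-hyperaemia flow curves with their AUC. Every intermediate
(per-subject FMD and HRV results, the cohort table) is persisted so each
reported number can be recomputed from the stage below it. The run is
deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError
from .hrv import band_powers, select_cleanest_segment
from .reliability import TrialMatrix, reliability_table
from .stats import group_summary, total_lung_capacity, validate_cohort
from .synthdata import (
    CohortSimParams, FmdSimParams, RrSimParams, VariableEffect,
    generate_cohort, generate_fmd_trace, generate_rr_series,
)
from .vascular import (
    FmdTrace, allometric_scaling_check, analyze_trace, hyperaemia_flow_curve,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "validate_fmd_result"]


# Default programmed cohort: a 12 + 12 pre/post trial in which training
# raises inspiratory pressure and voluntary ventilation but leaves lung
# volumes essentially unchanged.
DEFAULT_PULMONARY_EFFECTS: dict[str, VariableEffect] = {
    "FVC": VariableEffect(4.10, 0.49, 1.01, 0.99),
    "FEV1": VariableEffect(3.37, 0.45, 1.02, 1.00),
    "MIP": VariableEffect(48.0, 7.0, 1.31, 1.00),
    "MVV": VariableEffect(134.0, 14.0, 1.16, 1.03),
    "RV": VariableEffect(0.61, 0.12, 0.97, 1.01),
}


@dataclass
class StudyConfig:
    """Everything a study run needs: simulation ground truth + analysis options."""

    seed: int = 0
    output_dir: str | Path = "study_output"
    n_per_group: int = 12
    # -- cohort scalars ----------------------------------------------------
    pulmonary_effects: dict[str, VariableEffect] = field(
        default_factory=lambda: dict(DEFAULT_PULMONARY_EFFECTS)
    )
    within_subject_rho: float = 0.7
    # -- FMD stage ---------------------------------------------------------
    fmd_baseline_diameter: float = 0.30   # cm, cohort mean
    fmd_baseline_diameter_sd: float = 0.03
    fmd_percent_true: float = 8.0         # programmed %FMD, unchanged by training
    fmd_percent_sd: float = 1.5
    fmd_time_to_peak: float = 30.0        # s
    fmd_peak_velocity: float = 80.0       # cm/s at release (pre, both groups)
    # post-training multiplier on the hyperaemic velocity surge in the RMT
    # group; < 1 lowers cumulative SR while %FMD stays programmed
    sr_post_multiplier_rmt: float = 0.69
    sr_post_multiplier_sham: float = 1.0
    fmd_noise_sd_diameter: float = 0.002  # cm
    fmd_noise_sd_velocity: float = 1.0    # cm/s
    # -- HRV stage ---------------------------------------------------------
    hrv_mean_rr: float = 0.92             # s  (~65 bpm)
    hrv_lf_amplitude: float = 0.025       # s
    hrv_hf_amplitude: float = 0.028       # s
    hrv_noise_sd: float = 0.01            # s
    hrv_duration: float = 600.0           # s recorded; 300 s analyzed
    # -- analysis options --------------------------------------------------
    smooth_window: float = 3.0            # s, diameter peak smoothing
    alpha: float = 0.05
    icc_form: str = "consistency"
    sem_method: str = "sd_pooled"
    segment_length: float = 300.0
    resample_hz: float = 4.0
    flow_bin_width: float = 2.0
    # test-retest correlation used for the reliability (trial 1/trial 2) stage
    reliability_rho: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a config; unspecified keys keep their defaults."""
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        effects = raw.pop("pulmonary_effects", None)
        cfg = cls(**raw)
        if effects is not None:
            cfg.pulmonary_effects = {
                name: VariableEffect(*vals) for name, vals in effects.items()
            }
        return cfg


@dataclass
class StudyReport:
    """Report bundle of one study run (tables also persisted as CSV)."""

    reliability: pd.DataFrame
    pulmonary: pd.DataFrame
    hrv: pd.DataFrame
    fmd_summary: pd.DataFrame
    flow_auc: pd.DataFrame
    cohort: pd.DataFrame
    fmd_results: pd.DataFrame
    hrv_results: pd.DataFrame
    scaling_valid: bool
    output_dir: Path


def validate_fmd_result(
    baselines: Sequence[float], peaks: Sequence[float], alpha: float = 0.05
) -> bool:
    """Cohort-level gate: is ratio scaling (%FMD) statistically adequate?

    With fewer than 3 diameter pairs the regression is undefined; the
    validation is skipped (logged) and treated as a pass-through so that
    %FMD columns are still emitted.
    """
    if len(baselines) < 3:
        logger.warning("allometric validation skipped: fewer than 3 diameter pairs")
        return True
    result = allometric_scaling_check(baselines, peaks, alpha)
    if not result.ratio_scaling_valid:
        logger.warning(
            "ratio scaling questionable: slope CI upper limit %.3f < 1; "
            "%%FMD columns are flagged, not suppressed", result.ci_high,
        )
    return result.ratio_scaling_valid


def _fmd_stage(cfg: StudyConfig, seeds: np.random.SeedSequence):
    """Per-subject FMD traces and results for every group x time cell."""
    rng = np.random.default_rng(seeds)
    rows = []
    traces: dict[tuple[str, str], list[FmdTrace]] = {}
    for group, sr_mult in (("RMT", cfg.sr_post_multiplier_rmt),
                           ("SHAM", cfg.sr_post_multiplier_sham)):
        for s in range(cfg.n_per_group):
            subject = f"{group}{s + 1:02d}"
            base_d = rng.normal(cfg.fmd_baseline_diameter, cfg.fmd_baseline_diameter_sd)
            true_fmd = max(rng.normal(cfg.fmd_percent_true, cfg.fmd_percent_sd), 0.5)
            for time_label in ("pre", "post"):
                # the multiplier scales the whole post-release velocity
                # profile, so each subject's cumulative SR (and hyperaemic
                # flow) scales by exactly this factor
                mult = sr_mult if time_label == "post" else 1.0
                params = FmdSimParams(
                    baseline_diameter=max(base_d, 0.1),
                    fmd_percent=true_fmd,
                    time_to_peak=cfg.fmd_time_to_peak,
                    baseline_velocity=10.0 * mult,
                    peak_velocity=cfg.fmd_peak_velocity * mult,
                    sample_rate=10.0,
                    noise_sd_diameter=cfg.fmd_noise_sd_diameter,
                    noise_sd_velocity=cfg.fmd_noise_sd_velocity,
                    seed=int(rng.integers(2**31)),
                )
                trace = generate_fmd_trace(params)
                traces.setdefault((group, time_label), []).append(trace)
                res = analyze_trace(trace, smooth_window=cfg.smooth_window)
                rows.append({"subject": subject, "group": group,
                             "time": time_label, **res.to_dict()})
    return pd.DataFrame(rows), traces


def _hrv_stage(cfg: StudyConfig, seeds: np.random.SeedSequence) -> pd.DataFrame:
    """Per-subject HRV results for every group x time cell."""
    rng = np.random.default_rng(seeds)
    rows = []
    for group in ("RMT", "SHAM"):
        for s in range(cfg.n_per_group):
            subject = f"{group}{s + 1:02d}"
            mean_rr = rng.normal(cfg.hrv_mean_rr, 0.05)
            for time_label in ("pre", "post"):
                params = RrSimParams(
                    mean_rr=max(mean_rr, 0.4),
                    lf_amplitude=max(rng.normal(cfg.hrv_lf_amplitude, 0.005), 1e-4),
                    hf_amplitude=max(rng.normal(cfg.hrv_hf_amplitude, 0.005), 1e-4),
                    noise_sd=cfg.hrv_noise_sd,
                    duration=cfg.hrv_duration,
                    seed=int(rng.integers(2**31)),
                )
                series = generate_rr_series(params)
                segment = select_cleanest_segment(series, cfg.segment_length)
                res = band_powers(segment, resample_hz=cfg.resample_hz)
                rows.append({"subject": subject, "group": group,
                             "time": time_label, **res.to_dict()})
    return pd.DataFrame(rows)


def _reliability_stage(cfg: StudyConfig, seeds: np.random.SeedSequence) -> pd.DataFrame:
    """Trial 1 / trial 2 matrices simulated at the cohort's pre distributions."""
    effects = {name: VariableEffect(e.pre_mean, e.pre_sd, 1.0, 1.0)
               for name, e in cfg.pulmonary_effects.items()}
    effects["baseline_diameter"] = VariableEffect(
        cfg.fmd_baseline_diameter, cfg.fmd_baseline_diameter_sd, 1.0, 1.0)
    trial_cohort = generate_cohort(CohortSimParams(
        n_per_group=cfg.n_per_group, effects=effects,
        within_subject_rho=cfg.reliability_rho,
        seed=int(np.random.default_rng(seeds).integers(2**31)),
    ))
    matrices = []
    for name in effects:
        wide = trial_cohort.loc[trial_cohort["variable"] == name].pivot(
            index="subject", columns="time", values="value")
        matrices.append(TrialMatrix(
            values=wide[["pre", "post"]].to_numpy(), variable_name=name))
    return reliability_table(matrices, cfg.icc_form, cfg.sem_method)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full synthetic study and write the report bundle.

    Stages: cohort scalars (+ derived TLC), per-subject FMD analysis with
    the allometric ratio-scaling gate, per-subject HRV analysis,
    test-retest reliability, and the group statistics tables. All tables
    land in ``config.output_dir`` together with a JSON run log of every
    parameter applied.
    """
    if config.n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_fmd, s_hrv, s_rel = root.spawn(4)
    logger.info("study run: seed=%d, n=%d/group, output=%s",
                config.seed, config.n_per_group, out)

    # -- stage 1: pulmonary scalars ---------------------------------------
    cohort = generate_cohort(CohortSimParams(
        n_per_group=config.n_per_group, effects=config.pulmonary_effects,
        within_subject_rho=config.within_subject_rho,
        seed=int(np.random.default_rng(s_cohort).integers(2**31)),
    ))
    if {"RV", "FVC"}.issubset(config.pulmonary_effects):
        wide = cohort.pivot_table(index=["subject", "group", "time"],
                                  columns="variable", values="value",
                                  aggfunc="first").reset_index()
        tlc = wide.assign(
            variable="TLC",
            value=[total_lung_capacity(rv, fvc)
                   for rv, fvc in zip(wide["RV"], wide["FVC"])],
        )[["subject", "group", "time", "variable", "value"]]
        cohort = pd.concat([cohort, tlc], ignore_index=True)
    validate_cohort(cohort)

    # -- stage 2: FMD ------------------------------------------------------
    fmd_results, traces = _fmd_stage(config, s_fmd)
    scaling_valid = validate_fmd_result(
        fmd_results["baseline_diameter_cm"].tolist(),
        fmd_results["peak_diameter_cm"].tolist(), config.alpha)

    fmd_long = fmd_results.melt(
        id_vars=["subject", "group", "time"],
        value_vars=["fmd_percent", "cumulative_sr", "fmd_per_sr"],
        var_name="variable", value_name="value")
    fmd_summary = (
        fmd_results.groupby(["group", "time"])
        .agg(n=("subject", "size"),
             baseline_diameter_cm=("baseline_diameter_cm", "mean"),
             peak_diameter_cm=("peak_diameter_cm", "mean"),
             time_to_peak_s=("time_to_peak_s", "mean"),
             fmd_percent_mean=("fmd_percent", "mean"),
             fmd_percent_sd=("fmd_percent", "std"),
             cumulative_sr_mean=("cumulative_sr", "mean"),
             cumulative_sr_sd=("cumulative_sr", "std"),
             fmd_per_sr_mean=("fmd_per_sr", "mean"),
             fmd_per_sr_sd=("fmd_per_sr", "std"))
        .reset_index()
    )
    fmd_summary["ratio_scaling_valid"] = scaling_valid

    curves = []
    auc_rows = []
    for (group, time_label), cell_traces in sorted(traces.items()):
        curve, auc = hyperaemia_flow_curve(cell_traces, config.flow_bin_width)
        curve.insert(0, "group", group)
        curve.insert(1, "time", time_label)
        curves.append(curve)
        auc_rows.append({"group": group, "time": time_label,
                         "flow_auc_ml": auc, "n_traces": len(cell_traces)})
    flow_curves = pd.concat(curves, ignore_index=True)
    flow_auc = pd.DataFrame(auc_rows)

    # -- stage 3: HRV ------------------------------------------------------
    hrv_results = _hrv_stage(config, s_hrv)
    hrv_long = hrv_results.melt(
        id_vars=["subject", "group", "time"],
        value_vars=["lf_nu", "hf_nu", "lf_hf_ratio", "mean_hr_bpm"],
        var_name="variable", value_name="value")

    # -- stage 4: reliability ---------------------------------------------
    reliability = _reliability_stage(config, s_rel)

    # -- stage 5: group statistics ----------------------------------------
    pulmonary_table = group_summary(cohort, config.alpha)
    hrv_table = group_summary(hrv_long, config.alpha)
    fmd_stats = group_summary(fmd_long, config.alpha)
    fmd_stats["ratio_scaling_valid"] = scaling_valid

    # -- persist -----------------------------------------------------------
    tables = {
        "cohort.csv": cohort,
        "fmd_results.csv": fmd_results,
        "hrv_results.csv": hrv_results,
        "reliability_table.csv": reliability,
        "pulmonary_table.csv": pulmonary_table,
        "hrv_table.csv": hrv_table,
        "fmd_stats.csv": fmd_stats,
        "fmd_summary.csv": fmd_summary,
        "flow_curves.csv": flow_curves,
        "flow_auc.csv": flow_auc,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    run_log = {
        "version": __version__,
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in _jsonable(asdict(config)).items()},
        "scaling_valid": bool(scaling_valid),
        "tables": sorted(tables),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    logger.info("study run complete: %d tables in %s", len(tables), out)

    return StudyReport(
        reliability=reliability, pulmonary=pulmonary_table, hrv=hrv_table,
        fmd_summary=fmd_summary, flow_auc=flow_auc, cohort=cohort,
        fmd_results=fmd_results, hrv_results=hrv_results,
        scaling_valid=scaling_valid, output_dir=out,
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
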