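"""Synthetic data generators with known ground truth.

Three generators drive the test surface of the package:

* :func:`generate_fmd_trace` — a brachial diameter/velocity recording
  around cuff deflation: baseline plateau, post-release velocity surge
  decaying exponentially, diameter rising along a logistic to a
  programmed peak at a programmed time-to-peak.
* :func:`generate_rr_series` — an RR tachogram with sinusoidal LF and HF
  modulation of tunable amplitude plus Gaussian beat noise.
* :func:`generate_cohort` — a tidy two-group (RMT/SHAM) pre/post cohort
  table with multiplicative log-normal effects, emulating a
  respiratory-muscle-training trial.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hrv import RrSeries
from .vascular import FmdTrace

__all__ = [
    "FmdSimParams", "RrSimParams", "CohortSimParams", "VariableEffect",
    "generate_fmd_trace", "generate_rr_series", "generate_cohort",
]


# ---------------------------------------------------------------------------
# FMD trace
# ---------------------------------------------------------------------------

@dataclass
class FmdSimParams:
    """Ground-truth parameters of one synthetic FMD recording.

    The diameter curve is flat at ``baseline_diameter`` before deflation,
    rises along a normalized logistic to ``baseline_diameter *
    (1 + fmd_percent/100)``, holds a flat top of ``peak_plateau`` seconds
    centred at ``time_to_peak``, then relaxes exponentially toward
    baseline. The default plateau width equals the default smoothing
    window of the peak detector, so noiseless traces round-trip the
    programmed %FMD and time-to-peak exactly.
    """

    baseline_diameter: float = 0.30     # cm
    fmd_percent: float = 8.0            # programmed true %FMD
    time_to_peak: float = 30.0          # s post-deflation
    baseline_velocity: float = 10.0     # cm/s
    peak_velocity: float = 80.0         # cm/s at cuff release
    velocity_decay_tau: float = 30.0    # s, hyperaemia decay constant
    sample_rate: float = 10.0           # Hz
    occlusion_duration: float = 300.0   # s (cuff at 250 mmHg; metadata only)
    pre_deflation_window: float = 30.0  # s of baseline recording
    post_window: float = 120.0          # s recorded after deflation
    noise_sd_diameter: float = 0.0      # cm
    noise_sd_velocity: float = 0.0      # cm/s
    peak_plateau: float = 3.0           # s flat top at the peak
    diameter_recovery_tau: float = 40.0  # s, post-peak relaxation
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_diameter <= 0:
            raise ParameterError("baseline_diameter must be positive")
        if self.fmd_percent < 0:
            raise ParameterError("fmd_percent must be >= 0")
        if self.peak_velocity < self.baseline_velocity:
            raise ParameterError("peak_velocity must be >= baseline_velocity")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.noise_sd_diameter < 0 or self.noise_sd_velocity < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.time_to_peak - self.peak_plateau / 2 <= 0:
            raise ParameterError("time_to_peak must exceed half the peak plateau")
        if self.time_to_peak + self.peak_plateau / 2 >= self.post_window:
            raise ParameterError("peak plateau must end before the recording does")


def _logistic_rise(t: np.ndarray, t_end: float) -> np.ndarray:
    """Smooth monotone S-curve from exactly 0 at t=0 to exactly 1 at t_end."""
    k = 10.0 / t_end
    raw = 1.0 / (1.0 + np.exp(-k * (t - t_end / 2)))
    lo = 1.0 / (1.0 + np.exp(k * t_end / 2))
    hi = 1.0 / (1.0 + np.exp(-k * t_end / 2))
    return (raw - lo) / (hi - lo)


def generate_fmd_trace(params: FmdSimParams) -> FmdTrace:
    """Simulate one FMD recording spanning [-pre_deflation_window, +post_window]."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate
    n_pre = int(round(params.pre_deflation_window * params.sample_rate))
    n_post = int(round(params.post_window * params.sample_rate))
    time = (np.arange(n_pre + n_post + 1) - n_pre) * dt

    b = params.baseline_diameter
    amp = b * params.fmd_percent / 100.0
    rise_end = params.time_to_peak - params.peak_plateau / 2
    plateau_end = params.time_to_peak + params.peak_plateau / 2

    diameter = np.full_like(time, b)
    rising = (time > 0) & (time < rise_end)
    diameter[rising] = b + amp * _logistic_rise(time[rising], rise_end)
    on_peak = (time >= rise_end) & (time <= plateau_end)
    diameter[on_peak] = b + amp
    after = time > plateau_end
    diameter[after] = b + amp * np.exp(
        -(time[after] - plateau_end) / params.diameter_recovery_tau
    )

    velocity = np.full_like(time, params.baseline_velocity)
    post = time >= 0
    velocity[post] = params.baseline_velocity + (
        params.peak_velocity - params.baseline_velocity
    ) * np.exp(-time[post] / params.velocity_decay_tau)

    if params.noise_sd_diameter > 0:
        diameter = diameter + rng.normal(0, params.noise_sd_diameter, time.size)
    if params.noise_sd_velocity > 0:
        velocity = velocity + rng.normal(0, params.noise_sd_velocity, time.size)

    return FmdTrace(
        time=time, diameter=diameter, velocity=velocity,
        sample_rate=params.sample_rate,
        pre_deflation_window=params.pre_deflation_window,
    )


# ---------------------------------------------------------------------------
# RR series
# ---------------------------------------------------------------------------

@dataclass
class RrSimParams:
    """Ground truth for a sinusoidally modulated RR tachogram."""

    mean_rr: float = 0.9        # s
    lf_amplitude: float = 0.03  # s
    lf_freq: float = 0.10       # Hz, inside 0.04-0.15
    hf_amplitude: float = 0.03  # s
    hf_freq: float = 0.25       # Hz, inside 0.15-0.40
    noise_sd: float = 0.0       # s, per-beat Gaussian jitter
    duration: float = 600.0     # s; must allow a 5-min segment
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr <= 0:
            raise ParameterError("mean_rr must be positive")
        if self.duration < 300.0:
            raise ParameterError("duration must be >= 300 s (one 5-min segment)")
        if self.lf_amplitude < 0 or self.hf_amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("amplitudes and noise SD must be >= 0")
        if self.lf_amplitude > 0 and not (0.04 <= self.lf_freq <= 0.15):
            raise ParameterError("lf_freq must lie in the LF band 0.04-0.15 Hz")
        if self.hf_amplitude > 0 and not (0.15 <= self.hf_freq <= 0.40):
            raise ParameterError("hf_freq must lie in the HF band 0.15-0.40 Hz")


def generate_rr_series(params: RrSimParams) -> RrSeries:
    """Simulate beats until ``duration``: RR_i evaluated at cumulative time t_i.

    RR_i = mean_rr + lf_amp sin(2 pi f_lf t_i) + hf_amp sin(2 pi f_hf t_i)
    + N(0, noise_sd). Non-positive draws are redrawn (not clipped) to
    avoid spectral artifacts.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rr, beat_time = [], []
    t = 0.0
    while t < params.duration:
        base = (
            params.mean_rr
            + params.lf_amplitude * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amplitude * np.sin(2 * np.pi * params.hf_freq * t)
        )
        interval = base + (rng.normal(0, params.noise_sd) if params.noise_sd > 0 else 0.0)
        while interval <= 0:
            interval = base + rng.normal(0, params.noise_sd)
        t += interval
        rr.append(interval)
        beat_time.append(t)
    return RrSeries(rr=np.array(rr), beat_time=np.array(beat_time))


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

class VariableEffect(NamedTuple):
    """Programmed pre distribution and post/pre multipliers for one variable."""

    pre_mean: float
    pre_sd: float
    rmt_effect: float = 1.0   # multiplicative post/pre effect in the RMT group
    sham_effect: float = 1.0  # same for SHAM


@dataclass
class CohortSimParams:
    """Ground truth for a two-group (RMT/SHAM) pre/post cohort."""

    n_per_group: int = 12
    effects: Mapping[str, VariableEffect] = field(default_factory=dict)
    within_subject_rho: float = 0.7  # pre/post correlation on the log scale
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not -1.0 <= self.within_subject_rho <= 1.0:
            raise ParameterError("|within_subject_rho| must be <= 1")
        for name, eff in self.effects.items():
            e = VariableEffect(*eff)
            if e.pre_mean <= 0:
                raise ParameterError(f"{name}: pre_mean must be positive")
            if e.pre_sd < 0:
                raise ParameterError(f"{name}: pre_sd must be >= 0")
            if e.rmt_effect <= 0 or e.sham_effect <= 0:
                raise ParameterError(f"{name}: effects must be positive multipliers")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Tidy cohort table: subject, group, time, variable, value.

    Values are log-normal: for each variable the (log pre, log post) pair
    of a subject is bivariate normal with correlation
    ``within_subject_rho`` and a common log-SD matched so the marginal
    mean/SD equal the programmed pre distribution; the group's post
    multiplier shifts the log mean, so mean(post)/mean(pre) equals the
    programmed effect. Keeping everything multiplicative preserves
    positivity of physiological variables.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rho = params.within_subject_rho
    rows = []
    for group, eff_idx in (("RMT", 2), ("SHAM", 3)):
        for s in range(params.n_per_group):
            subject = f"{group}{s + 1:02d}"
            for name, eff in params.effects.items():
                e = VariableEffect(*eff)
                sigma2 = np.log1p((e.pre_sd / e.pre_mean) ** 2)
                sigma = np.sqrt(sigma2)
                mu = np.log(e.pre_mean) - sigma2 / 2
                z1 = rng.standard_normal()
                z2 = rng.standard_normal()
                log_pre = mu + sigma * z1
                log_post = (
                    mu + np.log(e[eff_idx])
                    + sigma * (rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * z2)
                )
                rows.append((subject, group, "pre", name, float(np.exp(log_pre))))
                rows.append((subject, group, "post", name, float(np.exp(log_post))))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "variable", "value"])
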