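"""Flow-mediated dilation (FMD) and brachial hemodynamics.

Implements the vascular arithmetic of an FMD study: baseline and peak
diameter extraction from a diameter/velocity time series, %FMD, blood
flow, shear rate (SR), cumulative SR by the trapezoidal rule, the
shear-normalized %FMD/SR ratio, vascular conductance, the allometric
scaling check for ratio-based FMD, reactive-hyperaemia flow curves, and
windowed averaging of beat-to-beat hemodynamics.

Conventions: time is in seconds with t = 0 at cuff deflation; diameter
in cm; mean blood velocity in cm/s; flow in ml/min; shear rate in 1/s.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FmdTrace",
    "FmdResult",
    "HemodynamicSample",
    "ScalingCheckResult",
    "baseline_diameter",
    "peak_diameter",
    "fmd_percent",
    "blood_flow",
    "shear_rate",
    "cumulative_shear_rate",
    "normalized_fmd",
    "vascular_conductance",
    "allometric_scaling_check",
    "hyperaemia_flow_curve",
    "windowed_hemodynamics",
    "analyze_trace",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FmdTrace:
    """Synchronized brachial diameter / velocity recording around cuff release.

    ``time`` is strictly increasing with t = 0 at cuff deflation; the
    recording conventionally spans [-pre_deflation_window, +120 s].
    """

    time: np.ndarray            # s
    diameter: np.ndarray        # cm
    velocity: np.ndarray        # cm/s (mean blood velocity)
    sample_rate: float          # Hz
    pre_deflation_window: float = 30.0  # s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (self.time.shape == self.diameter.shape == self.velocity.shape):
            raise DomainError("time, diameter and velocity must have equal length")
        if self.time.size < 2:
            raise InsufficientDataError("trace needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        if np.any(self.diameter <= 0):
            raise DomainError("diameter must be positive at every sample")
        if self.pre_deflation_window <= 0:
            raise DomainError("pre_deflation_window must be positive")

    # ---- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV (time_s, diameter_cm, velocity_cm_s) with metadata header."""
        header = (
            f"# sample_rate_hz={self.sample_rate!r}\n"
            f"# pre_deflation_window_s={self.pre_deflation_window!r}\n"
            "# deflation_time_s=0.0\n"
        )
        df = pd.DataFrame(
            {"time_s": self.time, "diameter_cm": self.diameter,
             "velocity_cm_s": self.velocity}
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FmdTrace":
        meta: dict[str, float] = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = float(val)
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        time = df["time_s"].to_numpy()
        sr = meta.get("sample_rate_hz", 1.0 / float(np.median(np.diff(time))))
        pre = meta.get("pre_deflation_window_s", max(-time[0], 1.0))
        return cls(time=time, diameter=df["diameter_cm"].to_numpy(),
                   velocity=df["velocity_cm_s"].to_numpy(),
                   sample_rate=sr, pre_deflation_window=pre)


@dataclass
class FmdResult:
    """Derived FMD metrics for one recording."""

    baseline_diameter: float    # cm
    peak_diameter: float        # cm
    time_to_peak: float         # s post-deflation
    fmd_percent: float          # %
    cumulative_sr: float        # dimensionless (1/s integrated over s)
    fmd_per_sr: float           # % per unit cumulative SR
    flow_series: np.ndarray = field(repr=False, default=None)  # ml/min
    flow_auc: float = float("nan")  # ml (time in minutes)

    def to_dict(self) -> dict:
        return {
            "baseline_diameter_cm": self.baseline_diameter,
            "peak_diameter_cm": self.peak_diameter,
            "time_to_peak_s": self.time_to_peak,
            "fmd_percent": self.fmd_percent,
            "cumulative_sr": self.cumulative_sr,
            "fmd_per_sr": self.fmd_per_sr,
            "flow_auc_ml": self.flow_auc,
        }


@dataclass
class HemodynamicSample:
    """Averaged central/peripheral hemodynamics over one time window.

    ``co`` (l/min) is always recomputed as sv*heart_rate/1000 and ``bvc``
    (ml/min/mmHg) as blood_flow/map, so the derived fields stay consistent
    with the averaged primitives.
    """

    heart_rate: float           # bpm
    map: float                  # mmHg (mean arterial pressure)
    sv: float                   # ml (stroke volume)
    blood_flow: float           # ml/min
    diameter: float = float("nan")   # cm
    sr: float = float("nan")         # 1/s

    @property
    def co(self) -> float:
        """Cardiac output, l/min."""
        return self.sv * self.heart_rate / 1000.0

    @property
    def bvc(self) -> float:
        """Brachial vascular conductance, ml/min/mmHg."""
        return vascular_conductance(self.blood_flow, self.map)


@dataclass
class ScalingCheckResult:
    """OLS slope of ln(peak) on ln(baseline) with its confidence interval.

    Expressing dilation as a ratio (%FMD) is adequate when the upper
    confidence limit of the slope reaches 1.
    """

    slope: float
    ci_low: float
    ci_high: float
    ratio_scaling_valid: bool
    n: int = 0
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Scalar formulas
# ---------------------------------------------------------------------------

def fmd_percent(baseline: float, peak: float) -> float:
    """Percent diameter change from baseline: (peak - baseline)/baseline * 100."""
    if baseline <= 0:
        raise DomainError("baseline diameter must be positive")
    return (peak - baseline) / baseline * 100.0


def blood_flow(v_mean: float, diameter: float) -> float:
    """Blood flow in ml/min: v_mean * pi * (diameter/2)^2 * 60."""
    if np.any(np.asarray(diameter) <= 0):
        raise DomainError("diameter must be positive")
    if np.any(np.asarray(v_mean) < 0):
        raise DomainError("negative mean velocity (flow reversal) is out of scope")
    return v_mean * math.pi * (diameter / 2.0) ** 2 * 60.0


def shear_rate(v_mean: float, diameter: float) -> float:
    """Wall shear rate estimate in 1/s: 8 * v_mean / diameter."""
    if np.any(np.asarray(diameter) <= 0):
        raise DomainError("diameter must be positive")
    return 8.0 * v_mean / diameter


def normalized_fmd(fmd_pct: float, cumulative_sr: float) -> float:
    """Shear-normalized dilation %FMD/SR."""
    if cumulative_sr <= 0:
        raise DomainError("cumulative shear rate must be positive for normalization")
    return fmd_pct / cumulative_sr


def vascular_conductance(flow: float, map_mmhg: float) -> float:
    """Vascular conductance: blood flow / mean arterial pressure."""
    if map_mmhg <= 0:
        raise DomainError("mean arterial pressure must be positive")
    return flow / map_mmhg


def _clipped_velocity(trace: FmdTrace) -> np.ndarray:
    """Velocity with retrograde (negative) samples clipped to zero."""
    v = trace.velocity
    if np.any(v < 0):
        logger.warning(
            "clipping %d retrograde velocity samples to 0", int(np.sum(v < 0))
        )
        v = np.clip(v, 0.0, None)
    return v


# ---------------------------------------------------------------------------
# Trace-level operations
# ---------------------------------------------------------------------------

def baseline_diameter(trace: FmdTrace) -> float:
    """Mean diameter over the pre-deflation window [-pre_deflation_window, 0)."""
    mask = (trace.time >= -trace.pre_deflation_window) & (trace.time < 0)
    if int(mask.sum()) < 5:
        raise InsufficientDataError(
            f"pre-deflation window holds {int(mask.sum())} samples; need >= 5"
        )
    return float(trace.diameter[mask].mean())


def smoothed_diameter(trace: FmdTrace, smooth_window: float = 3.0) -> np.ndarray:
    """Centered moving average of the diameter series (window in seconds).

    The window shrinks at the edges of the recording; smooth_window = 0
    returns the raw series.
    """
    if smooth_window <= 0:
        return trace.diameter.copy()
    n = int(round(smooth_window * trace.sample_rate))
    n = max(n + 1 if n % 2 == 0 else n, 1)  # odd sample count, centered
    return (
        pd.Series(trace.diameter)
        .rolling(n, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def peak_diameter(
    trace: FmdTrace, smooth_window: float = 3.0
) -> tuple[float, float]:
    """Maximum smoothed diameter after cuff release and its time.

    Ties resolve to the earliest time. Returns (peak_cm, time_to_peak_s).
    """
    post = trace.time > 0
    if not np.any(post):
        raise InsufficientDataError("no post-deflation samples")
    smooth = smoothed_diameter(trace, smooth_window)[post]
    idx = int(np.argmax(smooth))  # argmax returns the first maximum
    return float(smooth[idx]), float(trace.time[post][idx])


def cumulative_shear_rate(
    trace: FmdTrace, t_release: float = 0.0, t_peak: float | None = None
) -> float:
    """Trapezoidal integral of the shear-rate series on [t_release, t_peak].

    This is the cumulative shear-rate stimulus (SR AUC) from cuff release
    to peak dilation.
    """
    if t_peak is None:
        _, t_peak = peak_diameter(trace)
    if t_peak <= t_release:
        raise DomainError("t_peak must be after t_release")
    if t_release < trace.time[0] or t_peak > trace.time[-1]:
        raise InsufficientDataError("integration bounds outside the recording")
    mask = (trace.time >= t_release) & (trace.time <= t_peak)
    if int(mask.sum()) < 2:
        raise InsufficientDataError("fewer than 2 samples between release and peak")
    sr = shear_rate(_clipped_velocity(trace)[mask], trace.diameter[mask])
    return float(np.trapezoid(sr, trace.time[mask]))


def flow_series(trace: FmdTrace) -> np.ndarray:
    """Per-sample blood flow (ml/min), retrograde velocity clipped to zero."""
    return blood_flow(_clipped_velocity(trace), trace.diameter)


def analyze_trace(
    trace: FmdTrace,
    smooth_window: float = 3.0,
    post_window: float = 120.0,
) -> FmdResult:
    """Full single-recording FMD analysis.

    Computes baseline and peak diameter, %FMD, cumulative SR from release
    to peak, %FMD/SR, the hyperaemic flow series and its AUC over the
    post-release window (time converted to minutes, so the AUC is in ml).
    """
    base = baseline_diameter(trace)
    peak, ttp = peak_diameter(trace, smooth_window)
    pct = fmd_percent(base, peak)
    cum_sr = cumulative_shear_rate(trace, 0.0, ttp)
    flows = flow_series(trace)
    post = (trace.time >= 0) & (trace.time <= post_window)
    auc = float(np.trapezoid(np.clip(flows[post], 0, None), trace.time[post] / 60.0))
    return FmdResult(
        baseline_diameter=base,
        peak_diameter=peak,
        time_to_peak=ttp,
        fmd_percent=pct,
        cumulative_sr=cum_sr,
        fmd_per_sr=normalized_fmd(pct, cum_sr) if cum_sr > 0 else float("nan"),
        flow_series=flows,
        flow_auc=auc,
    )


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def allometric_scaling_check(
    baselines: Sequence[float],
    peaks: Sequence[float],
    alpha: float = 0.05,
) -> ScalingCheckResult:
    """Check whether ratio scaling (%FMD) is statistically adequate.

    Regresses ln(peak) on ln(baseline) by OLS and computes the two-sided
    (1 - alpha) CI of the slope with a t distribution on n - 2 df. Ratio
    scaling is considered valid when the upper confidence limit >= 1.
    """
    b = np.asarray(baselines, dtype=float)
    p = np.asarray(peaks, dtype=float)
    if b.shape != p.shape:
        raise DomainError("baselines and peaks must have equal length")
    n = b.size
    if n < 3:
        raise InsufficientDataError("allometric check needs >= 3 paired diameters")
    if np.any(b <= 0) or np.any(p <= 0):
        raise DomainError("diameters must be positive for log transformation")
    res = sps.linregress(np.log(b), np.log(p))
    tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    lo = res.slope - tcrit * stderr
    hi = res.slope + tcrit * stderr
    # tolerance absorbs float roundoff when residuals are ~0 and the CI is
    # degenerate at the slope itself
    return ScalingCheckResult(
        slope=float(res.slope), ci_low=float(lo), ci_high=float(hi),
        ratio_scaling_valid=bool(hi >= 1.0 - 1e-9), n=n, alpha=alpha,
    )


def hyperaemia_flow_curve(
    traces: Sequence[FmdTrace],
    bin_width: float = 2.0,
    post_window: float = 120.0,
) -> tuple[pd.DataFrame, float]:
    """Binned mean reactive-hyperaemia flow curve across recordings.

    Each trace's per-sample flow is averaged within time bins covering
    [0, post_window]; bins are then averaged across traces. The AUC is
    the trapezoidal integral of the mean curve (first/last bin values
    extended to the window edges), with time in minutes so the AUC is ml.

    Returns (DataFrame with columns time_s, flow_ml_min, n_traces, AUC_ml).
    """
    if len(traces) == 0:
        raise InsufficientDataError("need at least one trace")
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    edges = np.arange(0.0, post_window + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    per_trace = []
    for tr in traces:
        flows = flow_series(tr)
        mask = (tr.time >= 0) & (tr.time <= post_window)
        idx = np.clip(np.digitize(tr.time[mask], edges) - 1, 0, len(centers) - 1)
        sums = np.bincount(idx, weights=flows[mask], minlength=len(centers))
        counts = np.bincount(idx, minlength=len(centers))
        with np.errstate(invalid="ignore"):
            per_trace.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    stacked = np.vstack(per_trace)
    mean_curve = np.nanmean(stacked, axis=0)
    n_traces = np.sum(~np.isnan(stacked), axis=0)
    valid = ~np.isnan(mean_curve)
    t = centers[valid]
    y = np.clip(mean_curve[valid], 0, None)
    # extend the step ends to the window edges so a constant F integrates to
    # exactly F * post_window
    t_ext = np.concatenate(([0.0], t, [post_window]))
    y_ext = np.concatenate(([y[0]], y, [y[-1]]))
    auc = float(np.trapezoid(y_ext, t_ext / 60.0))
    curve = pd.DataFrame(
        {"time_s": centers, "flow_ml_min": mean_curve, "n_traces": n_traces}
    )
    return curve, auc


def windowed_hemodynamics(
    samples: pd.DataFrame,
    baseline_window: float = 30.0,
    tail_window: float = 10.0,
) -> tuple[HemodynamicSample, HemodynamicSample]:
    """Average beat-to-beat hemodynamics over protocol windows.

    ``samples`` is a time-stamped stream with columns ``time_s``,
    ``heart_rate``, ``map``, ``sv`` and either ``blood_flow`` or both
    ``velocity`` and ``diameter``. The baseline window is the first
    ``baseline_window`` seconds of the stream, the exercise window the
    last ``tail_window`` seconds; derived quantities (CO, BVC, SR) are
    recomputed from the averaged primitives.
    """
    required = {"time_s", "heart_rate", "map", "sv"}
    if not required.issubset(samples.columns):
        raise DomainError(f"stream must carry columns {sorted(required)}")
    t = samples["time_s"].to_numpy(dtype=float)
    t0, t1 = t.min(), t.max()
    if t1 - t0 < baseline_window + tail_window:
        raise InsufficientDataError("stream shorter than baseline + tail windows")

    def _mean_sample(mask: np.ndarray) -> HemodynamicSample:
        if not np.any(mask):
            raise InsufficientDataError("window holds no samples")
        win = samples.loc[mask]
        diameter = float(win["diameter"].mean()) if "diameter" in win else float("nan")
        if "blood_flow" in win:
            flow = float(win["blood_flow"].mean())
        else:
            v = float(win["velocity"].mean())
            flow = blood_flow(v, diameter)
        sr = float("nan")
        if "velocity" in win and "diameter" in win:
            sr = shear_rate(float(win["velocity"].mean()), diameter)
        return HemodynamicSample(
            heart_rate=float(win["heart_rate"].mean()),
            map=float(win["map"].mean()),
            sv=float(win["sv"].mean()),
            blood_flow=flow,
            diameter=diameter,
            sr=sr,
        )

    baseline = _mean_sample(t <= t0 + baseline_window)
    tail = _mean_sample(t >= t1 - tail_window)
    return baseline, tail
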