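"""Frequency-domain heart-rate-variability analysis.

Takes an RR-interval tachogram, selects the cleanest 5-minute segment,
resamples it to an even grid, and integrates a Welch power spectrum over
the conventional bands: VLF 0.01-0.04 Hz, LF 0.04-0.15 Hz (sympathetic /
baroreflex), HF 0.15-0.4 Hz (vagal). Band powers are reported in ms^2
together with normalized units lf/(lf+hf)*100 and the LF/HF ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy.interpolate import CubicSpline

from .errors import DomainError, InsufficientDataError

__all__ = ["RrSeries", "HrvResult", "select_cleanest_segment", "band_powers",
           "mean_heart_rate", "DEFAULT_BANDS"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.01, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: Below this total LF+HF power (ms^2) a spectrum is treated as degenerate.
_DEGENERATE_POWER = 1e-10


@dataclass
class RrSeries:
    """An RR tachogram: interbeat intervals and cumulative beat times (s)."""

    rr: np.ndarray          # s, one value per beat
    beat_time: np.ndarray   # s, cumulative time of each beat

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        if self.rr.shape != self.beat_time.shape:
            raise DomainError("rr and beat_time must have equal length")
        if np.any(self.rr <= 0):
            raise DomainError("RR intervals must be positive")
        if np.any(np.diff(self.beat_time) <= 0):
            raise DomainError("beat times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.beat_time[-1] - self.beat_time[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"beat_time_s": self.beat_time, "rr_s": self.rr}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RrSeries":
        df = pd.read_csv(path)
        return cls(rr=df["rr_s"].to_numpy(), beat_time=df["beat_time_s"].to_numpy())


@dataclass
class HrvResult:
    """Band-power summary of one analyzed segment."""

    lf_power: float         # ms^2
    hf_power: float         # ms^2
    vlf_power: float        # ms^2
    lf_nu: float            # normalized units, lf/(lf+hf)*100
    hf_nu: float
    lf_hf_ratio: float
    segment_start: float    # s, start time of the analyzed segment
    mean_hr: float          # bpm
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "lf_power_ms2": self.lf_power, "hf_power_ms2": self.hf_power,
            "vlf_power_ms2": self.vlf_power, "lf_nu": self.lf_nu,
            "hf_nu": self.hf_nu, "lf_hf_ratio": self.lf_hf_ratio,
            "segment_start_s": self.segment_start, "mean_hr_bpm": self.mean_hr,
            "degenerate": self.degenerate,
        }


def mean_heart_rate(series: RrSeries) -> float:
    """Mean heart rate in bpm: 60 / mean(RR)."""
    if series.rr.size == 0:
        raise InsufficientDataError("empty RR series")
    return 60.0 / float(series.rr.mean())


def artifact_flags(
    series: RrSeries, threshold: float = 0.2, median_window: int = 11
) -> np.ndarray:
    """Boolean flag per beat: |delta RR| exceeds threshold * local median RR.

    The local median is a centered rolling median of the RR series
    (``median_window`` beats, shrinking at the edges). The first beat has
    no predecessor and is never flagged.
    """
    rr = pd.Series(series.rr)
    local_med = rr.rolling(median_window, center=True, min_periods=1).median()
    drr = np.abs(np.diff(series.rr, prepend=series.rr[0]))
    flags = drr > threshold * local_med.to_numpy()
    flags[0] = False
    return flags


def select_cleanest_segment(
    series: RrSeries,
    segment_length: float = 300.0,
    threshold: float = 0.2,
    median_window: int = 11,
) -> RrSeries:
    """Contiguous segment of ``segment_length`` s with the fewest artifacts.

    Candidate windows start at each beat; the artifact score is the count
    of flagged beats inside the window. Ties resolve to the lowest RR
    variance, then to the earliest start.
    """
    if series.duration < segment_length:
        raise InsufficientDataError(
            f"recording ({series.duration:.0f} s) shorter than the "
            f"requested segment ({segment_length:.0f} s)"
        )
    flags = artifact_flags(series, threshold, median_window)
    t = series.beat_time
    best: tuple[float, float, int] | None = None
    best_slice: slice | None = None
    for start in range(t.size):
        if t[-1] - t[start] < segment_length - 1e-9:
            break  # no later window can span the full length
        # first index whose beat time reaches t[start] + segment_length, so the
        # returned segment always spans >= segment_length
        stop = int(np.searchsorted(t, t[start] + segment_length - 1e-9, side="left")) + 1
        window = slice(start, stop)
        score = int(flags[window].sum())
        var = float(np.var(series.rr[window]))
        key = (score, var, start)
        if best is None or key < best:
            best, best_slice = key, window
    assert best_slice is not None
    return RrSeries(rr=series.rr[best_slice], beat_time=t[best_slice])


def band_powers(
    series: RrSeries,
    bands: dict[str, tuple[float, float]] | None = None,
    resample_hz: float = 4.0,
    welch_window_s: float = 120.0,
    overlap: float = 0.5,
    min_duration: float = 300.0,
) -> HrvResult:
    """Welch band powers of an RR segment.

    The tachogram (converted to ms) is cubic-spline interpolated onto an
    even ``resample_hz`` grid, mean-removed, and its PSD estimated with
    Hann-tapered Welch segments of ``welch_window_s`` seconds at
    ``overlap`` fractional overlap. Band powers are rectangle sums of the
    PSD over frequency bins with lo < f <= hi, so adjacent bands
    partition the analysis range exactly.

    A constant (or near-constant) segment yields a zero-power result with
    the normalized units and LF/HF ratio undefined and ``degenerate``
    set, rather than an exception.
    """
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    for name, (lo, hi) in bands.items():
        if not (0 <= lo < hi):
            raise DomainError(f"band {name!r} has invalid range ({lo}, {hi})")
    if series.duration < min_duration:
        raise InsufficientDataError(
            f"segment ({series.duration:.0f} s) shorter than {min_duration:.0f} s"
        )
    rr_ms = series.rr * 1000.0
    grid = np.arange(series.beat_time[0], series.beat_time[-1], 1.0 / resample_hz)
    even = CubicSpline(series.beat_time, rr_ms)(grid)
    even = even - even.mean()
    nperseg = min(int(welch_window_s * resample_hz), even.size)
    freqs, psd = spsig.welch(
        even, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend=False,
    )
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs > lo) & (freqs <= hi)
        return float(np.sum(psd[mask]) * df)

    powers = {name: band_power(lo, hi) for name, (lo, hi) in bands.items()}
    lf, hf = powers.get("lf", 0.0), powers.get("hf", 0.0)
    total = lf + hf
    if total < _DEGENERATE_POWER:
        lf_nu = hf_nu = ratio = float("nan")
        degenerate = True
    else:
        lf_nu = lf / total * 100.0
        hf_nu = hf / total * 100.0
        ratio = lf / hf if hf > 0 else float("inf")
        degenerate = False
    return HrvResult(
        lf_power=lf, hf_power=hf, vlf_power=powers.get("vlf", 0.0),
        lf_nu=lf_nu, hf_nu=hf_nu, lf_hf_ratio=ratio,
        segment_start=float(series.beat_time[0]),
        mean_hr=mean_heart_rate(series), degenerate=degenerate,
    )
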