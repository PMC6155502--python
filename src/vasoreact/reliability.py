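"""Inter-session reliability and sensitivity statistics.

Implements the test-retest chain used for trial-by-subject matrices:
two-way mixed-model intraclass correlation (ICC(3,1) consistency, with
the absolute-agreement ICC(2,1) behind a flag), the standard error of
measurement as a percentage of the grand mean (SEM%), the minimal
detectable change at 95% confidence (MDC95% = 1.96 * sqrt(2) * SEM%),
and the conventional qualitative ICC classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "TrialMatrix", "ReliabilityResult", "icc_two_way_mixed", "sem_percent",
    "mdc95_percent", "classify_icc", "analyze_matrix", "reliability_table",
]


@dataclass
class TrialMatrix:
    """Subjects x trials matrix of one variable (no missing cells)."""

    values: np.ndarray
    variable_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("trial matrix must be 2-D (subjects x trials)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise DomainError("need >= 2 subjects and >= 2 trials")
        if np.any(~np.isfinite(self.values)):
            raise DomainError("trial matrix must have no missing cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class ReliabilityResult:
    """ICC / SEM% / MDC95% summary for one variable."""

    variable: str
    icc: float
    sem_percent: float
    mdc95_percent: float
    icc_class: str
    trial_means: tuple[float, ...] = ()
    trial_sds: tuple[float, ...] = ()


def icc_two_way_mixed(m: TrialMatrix, form: str = "consistency") -> float:
    """Two-way mixed-model, single-measures intraclass correlation.

    ``form="consistency"`` gives ICC(3,1) =
    (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)
    from the two-way ANOVA decomposition with subjects as rows and trials
    as columns; ``form="agreement"`` gives the absolute-agreement
    ICC(2,1), which additionally charges the trial (session) variance.

    An all-equal matrix has no variance to apportion and returns 1.0 by
    convention (logged).
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0 and ms_err <= 0:
        logger.warning(
            "%s: all cells equal; ICC undefined, returning 1.0 by convention",
            m.variable_name or "matrix",
        )
        return 1.0
    if form == "consistency":
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    elif form == "agreement":
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
    else:
        raise DomainError(f"unknown ICC form {form!r}")
    return min(icc, 1.0)  # clamp float roundoff when MS_error ~ 0


def sem_percent(m: TrialMatrix, icc: float, method: str = "sd_pooled") -> float:
    """Standard error of measurement as a percentage of the grand mean.

    ``method="sd_pooled"`` (default): SEM = SD_pooled * sqrt(1 - ICC),
    with SD_pooled the square root of the mean per-trial variance — the
    standard companion of the MDC95 formula. ``method="mse"``: SEM =
    sqrt(MS_error) of the two-way decomposition; both agree to rounding
    on typical test-retest tables.
    """
    if icc > 1 + 1e-9:
        raise DomainError("ICC cannot exceed 1")
    grand = float(m.values.mean())
    if grand == 0:
        raise DomainError("grand mean is zero; SEM% undefined")
    if method == "sd_pooled":
        sd_pooled = math.sqrt(float(np.mean(np.var(m.values, axis=0, ddof=1))))
        sem = sd_pooled * math.sqrt(max(1.0 - icc, 0.0))
    elif method == "mse":
        x = m.values
        n, k = x.shape
        grand_m = x.mean()
        ss_err = (
            float(np.sum((x - grand_m) ** 2))
            - k * float(np.sum((x.mean(axis=1) - grand_m) ** 2))
            - n * float(np.sum((x.mean(axis=0) - grand_m) ** 2))
        )
        sem = math.sqrt(max(ss_err, 0.0) / ((n - 1) * (k - 1)))
    else:
        raise DomainError(f"unknown SEM method {method!r}")
    return 100.0 * sem / abs(grand)


def mdc95_percent(sem_pct: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * sqrt(2) * SEM%."""
    if sem_pct < 0:
        raise DomainError("SEM% must be >= 0")
    return 1.96 * math.sqrt(2.0) * sem_pct


def classify_icc(icc: float) -> str:
    """Qualitative reliability class.

    very high > 0.90; high in [0.70, 0.90]; moderate in [0.50, 0.70);
    low below 0.50. The printed band edges are treated as inclusive
    interval boundaries.
    """
    if icc > 0.90:
        return "very high"
    if icc >= 0.70:
        return "high"
    if icc >= 0.50:
        return "moderate"
    return "low"


def analyze_matrix(
    m: TrialMatrix, form: str = "consistency", sem_method: str = "sd_pooled"
) -> ReliabilityResult:
    """Full ICC -> SEM% -> MDC95% -> class chain for one trial matrix."""
    icc = icc_two_way_mixed(m, form)
    sem = sem_percent(m, icc, sem_method)
    return ReliabilityResult(
        variable=m.variable_name,
        icc=icc,
        sem_percent=sem,
        mdc95_percent=mdc95_percent(sem),
        icc_class=classify_icc(icc),
        trial_means=tuple(m.values.mean(axis=0)),
        trial_sds=tuple(np.std(m.values, axis=0, ddof=1)),
    )


def reliability_table(
    matrices: list[TrialMatrix],
    form: str = "consistency",
    sem_method: str = "sd_pooled",
) -> pd.DataFrame:
    """Reliability summary table (one row per variable)."""
    rows = []
    for m in matrices:
        r = analyze_matrix(m, form, sem_method)
        row: dict = {"variable": r.variable}
        for j, (mu, sd) in enumerate(zip(r.trial_means, r.trial_sds), start=1):
            row[f"trial{j}_mean"] = mu
            row[f"trial{j}_sd"] = sd
        row.update(
            icc=r.icc, sem_percent=r.sem_percent,
            mdc95_percent=r.mdc95_percent, icc_class=r.icc_class,
        )
        rows.append(row)
    return pd.DataFrame(rows)
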