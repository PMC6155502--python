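"""Test-retest reliability of two measurement sessions.

Simulates trial-1/trial-2 values for three variables with different
reliabilities and produces the ICC / SEM% / MDC95% table.
"""

import numpy as np

from vasoreact import TrialMatrix, reliability_table

rng = np.random.default_rng(3)
n = 12

def two_trials(mean, sd_between, sd_error):
    subject = rng.normal(mean, sd_between, size=(n, 1))
    return subject + rng.normal(0, sd_error, size=(n, 2))

matrices = [
    TrialMatrix(two_trials(130.0, 22.0, 4.5), "MVV", "l/min"),
    TrialMatrix(two_trials(0.29, 0.04, 0.002), "baseline diameter", "cm"),
    TrialMatrix(two_trials(290_000, 30_000, 27_000), "cumulative SR", "1/s"),
]
table = reliability_table(matrices)
print(table.round(3).to_string(index=False))
# ICC(3,1) apportions variance between subjects and measurement error;
# SEM% converts the error into percent of the mean, and MDC95% =
# 1.96*sqrt(2)*SEM% is the smallest change in an individual that exceeds
# measurement noise with 95% confidence. High between-subject spread with
# small error gives "very high" reliability; the noisy shear-rate variable
# drops to "moderate".
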