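"""Default cohort profiles for the synthetic-data generator.

These are the study conditions the package is calibrated to: a 100-subject
elderly cohort assessed once with eyes open and once with eyes closed on two
balance boards, with six-month retrospective fall history and six-month
prospective fall follow-up.  Group-conditional sway statistics (mean ± SD per
metric and condition, plus Romberg Quotient statistics) parameterise the
generator; group sizes and demographics are carried as metadata.

Faller groups
-------------
RF / RNF : retrospective fallers / non-fallers (six-month history).
PNF      : prospective non-fallers — RNF with complete follow-up, no falls.
PAF      : prospective all fallers — anyone who fell during follow-up.
PF       : prospective fallers — fallers among RNF with complete follow-up.
PSF, PMF : PF who fell exactly once / more than once.
"""

from __future__ import annotations

import pandas as pd

from .metrics import METRIC_NAMES

__all__ = [
    "GROUP_SIZES",
    "DEMOGRAPHICS",
    "SWAY_PROFILES",
    "RQ_PROFILES",
    "sway_profile_frame",
    "rq_profile_frame",
]

#: Subjects per faller group in the reference cohort.
GROUP_SIZES = {
    "RF": 24,
    "RNF": 76,
    "PNF": 47,
    "PAF": 42,
    "PF": 28,
    "PSF": 22,
    "PMF": 6,
}

#: Demographics per group: (n, male, female, age mean, age sd, height mean,
#: height sd, weight mean, weight sd).
DEMOGRAPHICS = pd.DataFrame(
    {
        "n": [24, 76, 47, 42, 28, 22, 6, 100],
        "male": [13, 31, 17, 22, 14, 11, 3, 44],
        "female": [11, 45, 30, 20, 14, 11, 3, 56],
        "age_mean": [76.3, 75.2, 75.3, 75.6, 75.0, 75.9, 71.8, 75.5],
        "age_sd": [7.0, 6.6, 5.5, 7.8, 8.2, 8.2, 8.1, 6.7],
        "height_mean": [165.2, 165.1, 164.8, 165.7, 165.7, 164.9, 168.7, 165.1],
        "height_sd": [10.3, 10.0, 10.5, 10.0, 9.3, 8.9, 10.9, 10.0],
        "weight_mean": [71.9, 73.1, 73.3, 72.3, 73.4, 69.9, 86.2, 72.8],
        "weight_sd": [14.3, 13.4, 13.6, 13.5, 13.2, 11.0, 13.2, 13.5],
    },
    index=["RF", "RNF", "PNF", "PAF", "PF", "PSF", "PMF", "All"],
)

# Per-group sway statistics: {group: {condition: {metric: (mean, sd)}}},
# metric order range_ap, range_ml, rms_ap, rms_ml, vel_ap, vel_ml, vel_vsm.
# Ranges/RMS in mm, velocities in mm/s.
def _cond(values):
    return dict(zip(METRIC_NAMES, values))


SWAY_PROFILES = {
    "PNF": {
        "EO": _cond([(21.42, 7.24), (14.98, 9.70), (4.12, 1.22), (2.80, 1.80),
                     (7.53, 1.93), (4.57, 1.57), (9.70, 2.34)]),
        "EC": _cond([(37.72, 12.99), (15.58, 7.09), (6.91, 2.35), (2.86, 1.20),
                     (15.11, 5.59), (5.83, 2.01), (17.26, 6.04)]),
    },
    "PAF": {
        "EO": _cond([(22.04, 5.81), (13.10, 8.90), (4.48, 1.21), (2.55, 1.77),
                     (7.75, 2.15), (4.62, 1.69), (9.86, 2.77)]),
        "EC": _cond([(34.21, 14.84), (14.92, 9.58), (6.57, 2.55), (2.84, 1.97),
                     (17.76, 13.40), (6.86, 5.37), (20.30, 15.05)]),
    },
    "PF": {
        "EO": _cond([(22.86, 5.47), (13.43, 9.97), (4.65, 1.25), (2.65, 1.94),
                     (7.75, 1.66), (4.63, 1.67), (9.84, 2.32)]),
        "EC": _cond([(34.00, 12.37), (14.32, 5.77), (6.51, 2.03), (2.72, 1.41),
                     (17.03, 8.39), (6.74, 4.53), (19.58, 9.82)]),
    },
    "PSF": {
        "EO": _cond([(22.97, 4.99), (14.24, 11.15), (4.71, 1.34), (2.80, 2.17),
                     (7.78, 1.74), (4.73, 1.84), (10.02, 2.39)]),
        "EC": _cond([(31.85, 11.12), (14.11, 6.33), (6.00, 1.72), (2.63, 1.52),
                     (15.66, 7.13), (6.73, 5.06), (18.30, 9.25)]),
    },
    "PMF": {
        "EO": _cond([(22.48, 7.52), (10.49, 1.22), (4.44, 0.96), (2.08, 0.41),
                     (7.67, 1.43), (4.28, 0.86), (9.21, 2.12)]),
        "EC": _cond([(41.91, 14.55), (15.09, 3.25), (8.38, 2.12), (3.07, 0.99),
                     (22.06, 11.31), (6.77, 1.89), (24.27, 11.31)]),
    },
}

#: Romberg Quotient statistics per group: {group: {metric: (mean, sd)}}.
RQ_PROFILES = {
    "PNF": _cond([(1.90, 0.79), (1.25, 0.61), (1.77, 0.65), (1.20, 0.55),
                  (2.04, 0.65), (1.34, 0.45), (1.81, 0.57)]),
    "PAF": _cond([(1.57, 0.51), (1.25, 0.51), (1.51, 0.48), (1.22, 0.54),
                  (2.18, 0.99), (1.42, 0.56), (1.99, 1.01)]),
    "PF": _cond([(1.53, 0.54), (1.22, 0.48), (1.46, 0.48), (1.18, 0.57),
                 (2.18, 0.97), (1.43, 0.57), (2.02, 1.07)]),
    "PSF": _cond([(1.40, 0.44), (1.16, 0.50), (1.32, 0.37), (1.10, 0.58),
                  (1.99, 0.71), (1.38, 0.60), (1.80, 0.67)]),
    "PMF": _cond([(1.98, 0.65), (1.45, 0.30), (1.95, 0.54), (1.49, 0.46),
                  (2.86, 1.51), (1.59, 0.39), (2.80, 1.83)]),
}


def sway_profile_frame() -> pd.DataFrame:
    """Sway profiles as a tidy frame (group, condition, metric, mean, sd)."""
    rows = []
    for group, conds in SWAY_PROFILES.items():
        for cond, metrics in conds.items():
            for metric, (mean, sd) in metrics.items():
                rows.append((group, cond, metric, mean, sd))
    return pd.DataFrame(rows, columns=["group", "condition", "metric", "mean", "sd"])


def rq_profile_frame() -> pd.DataFrame:
    """Romberg Quotient profiles as a tidy frame (group, metric, mean, sd)."""
    rows = [
        (group, metric, mean, sd)
        for group, metrics in RQ_PROFILES.items()
        for metric, (mean, sd) in metrics.items()
    ]
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "sd"])
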