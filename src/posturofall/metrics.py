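"""Sway outcome measures and Romberg Quotients.

Seven per-trial measures of quiet-stance postural steadiness are computed
from the CoP trajectory: absolute motion range and RMS distance from the
trial mean along the AP and ML axes, mean total-excursion velocity per axis,
and the mean resultant (vector sum magnitude, VSM) velocity combining both
axes.  The Romberg Quotient of a measure is its eyes-closed value divided by
its eyes-open value and quantifies reliance on vision for postural control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boards import CoPTrace

__all__ = [
    "METRIC_NAMES",
    "SwayMetrics",
    "TrialPair",
    "compute_metrics",
    "romberg",
    "percent_increase",
]

#: Canonical metric order used by every table in the package.
METRIC_NAMES = (
    "range_ap",
    "range_ml",
    "rms_ap",
    "rms_ml",
    "vel_ap",
    "vel_ml",
    "vel_vsm",
)

#: Human-readable labels for report tables.
METRIC_LABELS = {
    "range_ap": "CoP Range, AP (mm)",
    "range_ml": "CoP Range, ML (mm)",
    "rms_ap": "CoP RMS, AP (mm)",
    "rms_ml": "CoP RMS, ML (mm)",
    "vel_ap": "CoP Velocity, AP (mm/s)",
    "vel_ml": "CoP Velocity, ML (mm/s)",
    "vel_vsm": "CoP Velocity, VSM (mm/s)",
}

#: Denominator floor below which a ratio is reported as missing.
RATIO_FLOOR = 1e-9


@dataclass(frozen=True)
class SwayMetrics:
    """The seven sway outcome measures for one trial.

    Ranges and RMS in mm, velocities in mm/s; all non-negative.  The metric
    set obeys ``rms <= range`` per axis and the triangle inequality
    ``max(vel_ap, vel_ml) <= vel_vsm <= vel_ap + vel_ml``.
    """

    range_ap: float
    range_ml: float
    rms_ap: float
    rms_ml: float
    vel_ap: float
    vel_ml: float
    vel_vsm: float

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRIC_NAMES})

    @classmethod
    def from_mapping(cls, values) -> "SwayMetrics":
        return cls(**{m: float(values[m]) for m in METRIC_NAMES})

    def validate(self, rtol: float = 1e-9) -> None:
        """Raise if the metric-set invariants are violated."""
        s = self.as_series()
        if (s < 0).any():
            raise ValueError("sway metrics must be non-negative")
        slack = 1.0 + rtol
        if self.rms_ap > self.range_ap * slack or self.rms_ml > self.range_ml * slack:
            raise ValueError("RMS cannot exceed range")
        lo = max(self.vel_ap, self.vel_ml)
        hi = self.vel_ap + self.vel_ml
        if not (lo / slack <= self.vel_vsm <= hi * slack):
            raise ValueError("VSM velocity violates the triangle inequality")


@dataclass(frozen=True)
class TrialPair:
    """Eyes-open and eyes-closed metric sets for one subject."""

    subject_id: str
    eyes_open: SwayMetrics
    eyes_closed: SwayMetrics


def compute_metrics(cop: CoPTrace) -> SwayMetrics:
    """Compute the seven sway measures from a CoP trajectory.

    Range is max minus min per axis; RMS is the root-mean-square deviation
    from the per-trial mean per axis; velocities are total excursion (sum of
    absolute successive differences; Euclidean step lengths for VSM) divided
    by the trial duration (N-1)/fs, so a straight path of length L yields
    exactly L/duration.
    """
    if cop.n_samples < 2:
        raise ValueError("at least 2 samples are required to compute sway metrics")
    ap, ml = cop.ap, cop.ml
    duration = cop.duration
    d_ap, d_ml = np.diff(ap), np.diff(ml)
    return SwayMetrics(
        range_ap=float(np.ptp(ap)),
        range_ml=float(np.ptp(ml)),
        rms_ap=float(np.sqrt(np.mean((ap - ap.mean()) ** 2))),
        rms_ml=float(np.sqrt(np.mean((ml - ml.mean()) ** 2))),
        vel_ap=float(np.sum(np.abs(d_ap)) / duration),
        vel_ml=float(np.sum(np.abs(d_ml)) / duration),
        vel_vsm=float(np.sum(np.hypot(d_ap, d_ml)) / duration),
    )


def romberg(pair: TrialPair, floor: float = RATIO_FLOOR) -> pd.Series:
    """Romberg Quotient per metric: eyes-closed / eyes-open.

    Entries whose eyes-open value is below ``floor`` are NaN (an undefined
    ratio is reported as missing, never as zero).
    """
    eo = pair.eyes_open.as_series()
    ec = pair.eyes_closed.as_series()
    rq = ec / eo
    rq[eo < floor] = math.nan
    return rq


def percent_increase(pair: TrialPair, floor: float = RATIO_FLOOR) -> pd.Series:
    """Per-metric percent change from eyes open to eyes closed.

    100·(EC − EO)/EO per metric; NaN where the eyes-open value is below
    ``floor``.  Group summaries should average these per-subject percentages
    (mean of percentages, not percentage of group means).
    """
    eo = pair.eyes_open.as_series()
    ec = pair.eyes_closed.as_series()
    pct = 100.0 * (ec - eo) / eo
    pct[eo < floor] = math.nan
    return pct
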