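"""Cohort container and faller-group labelling.

A cohort couples per-subject metadata (demographics, six-month retrospective
fall count, six-month prospective fall count) with the eyes-open and
eyes-closed sway-metric tables.  Prospective fall counts may be missing for
subjects lost to follow-up; such subjects are excluded from every prospective
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

__all__ = ["Cohort", "GroupLabeling", "label_groups", "GROUP_NAMES"]

GROUP_NAMES = ("RF", "RNF", "PNF", "PAF", "PF", "PSF", "PMF")

METADATA_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "retro_falls",
    "pro_falls",
)


@dataclass
class Cohort:
    """Subject metadata plus per-condition sway-metric tables.

    Parameters
    ----------
    subjects : DataFrame
        One row per subject with columns ``subject_id``, ``sex``, ``age``,
        ``height``, ``weight``, ``retro_falls`` (>= 0) and ``pro_falls``
        (>= 0, NaN if lost to follow-up).
    metrics_eo, metrics_ec : DataFrame
        Indexed by ``subject_id`` with the seven metric columns.
    """

    subjects: pd.DataFrame
    metrics_eo: pd.DataFrame = field(default=None)
    metrics_ec: pd.DataFrame = field(default=None)

    def __post_init__(self):
        subj = self.subjects
        if subj["subject_id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        retro = subj["retro_falls"]
        if retro.isna().any() or (retro < 0).any():
            raise ValueError("retrospective fall counts must be >= 0 and present")
        pro = subj["pro_falls"]
        if (pro.dropna() < 0).any():
            raise ValueError("prospective fall counts must be >= 0 or missing")
        for tbl in (self.metrics_eo, self.metrics_ec):
            if tbl is not None:
                missing = [m for m in METRIC_NAMES if m not in tbl.columns]
                if missing:
                    raise ValueError(f"metric table missing columns: {missing}")

    @property
    def subject_ids(self) -> pd.Index:
        return pd.Index(self.subjects["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def rq_table(self) -> pd.DataFrame:
        """Per-subject Romberg Quotients (EC/EO per metric); NaN where EO ~ 0."""
        eo = self.metrics_eo.loc[self.subject_ids, METRIC_NAMES]
        ec = self.metrics_ec.loc[self.subject_ids, METRIC_NAMES]
        rq = ec / eo
        return rq.where(eo >= 1e-9, np.nan)


@dataclass(frozen=True)
class GroupLabeling:
    """Boolean membership flags per subject for the seven faller groups."""

    flags: pd.DataFrame

    def members(self, group: str) -> pd.Index:
        return self.flags.index[self.flags[group]]

    def sizes(self) -> pd.Series:
        return self.flags.sum().astype(int)


def label_groups(cohort: Cohort) -> GroupLabeling:
    """Assign retrospective and prospective faller-group memberships.

    RF / RNF split on retrospective fall count (>= 1 / 0).  Prospective
    groups require a complete follow-up: PAF is any subject with >= 1
    prospective fall; PF restricts PAF to retrospective non-fallers; PSF and
    PMF split PF at exactly one versus more than one fall; PNF is
    retrospective non-fallers with complete follow-up and zero prospective
    falls.  Retrospective fallers never enter PF/PSF/PMF/PNF (a pre-assessment
    fall history already marks them at risk and may alter their sway).
    """
    subj = cohort.subjects.set_index("subject_id")
    retro = subj["retro_falls"].to_numpy()
    pro = subj["pro_falls"].to_numpy(dtype=float)
    followed = ~np.isnan(pro)
    rf = retro >= 1
    rnf = ~rf
    paf = followed & (pro >= 1)
    pf = rnf & paf
    flags = pd.DataFrame(
        {
            "RF": rf,
            "RNF": rnf,
            "PNF": rnf & followed & (pro == 0),
            "PAF": paf,
            "PF": pf,
            "PSF": pf & (pro == 1),
            "PMF": pf & (pro >= 2),
        },
        index=subj.index,
    )
    return GroupLabeling(flags=flags)
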