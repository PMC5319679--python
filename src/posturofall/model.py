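"""Cohort-level fall-risk analysis as a fitted model.

:class:`FallRiskModel` couples a cohort (metadata + per-condition sway
metrics) with the analysis settings; :meth:`FallRiskModel.fit` runs the full
workflow — Romberg Quotients, eyes-open/eyes-closed condition comparisons per
faller group, faller-versus-non-faller group comparisons, and the three
cut-off-score constructions on every variable that separates a faller group
from the prospective non-fallers — and returns a :class:`FallRiskResults`
bundle with report tables, a text ``summary()`` and a JSON-ready dict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boards import TrialConfig, preprocess_trial, read_force_table
from .cohort import Cohort, GroupLabeling, label_groups
from .cutoffs import (
    CutoffScore,
    DiscriminantResults,
    LinearDiscriminantCutoff,
    RocCutoff,
    classify_and_report,
    clinical_cutoff,
)
from .metrics import METRIC_NAMES, compute_metrics
from .stats import independent_group_compare, paired_condition_compare

__all__ = ["FallRiskModel", "FallRiskResults", "load_trace_cohort"]

logger = logging.getLogger("posturofall")

#: Faller-group contrasts analysed against their non-faller reference.
CONTRASTS = (
    ("PAF", "PNF"),
    ("PF", "PNF"),
    ("PSF", "PNF"),
    ("PMF", "PNF"),
    ("RF", "RNF"),
)

#: Variable blocks screened for group differences: condition-specific
#: metrics and Romberg Quotients.
BLOCKS = ("EO", "EC", "RQ")


def _block_table(cohort: Cohort, rq: pd.DataFrame, block: str) -> pd.DataFrame:
    if block == "EO":
        return cohort.metrics_eo
    if block == "EC":
        return cohort.metrics_ec
    return rq


@dataclass
class FallRiskResults:
    """Fitted analysis bundle.

    Attributes
    ----------
    rq : DataFrame
        Per-subject Romberg Quotients.
    condition_comparison : DataFrame
        Per group and metric: EO/EC means +- SD, routed paired test, p-value,
        and the mean +- SD of per-subject percent increases.
    group_comparison : DataFrame
        Per contrast, block and metric: group means +- SD, routed independent
        test and p-value.
    cutoff_tables : dict[str, DataFrame]
        Per contrast: clinical and ROC cut-off rows (threshold, direction,
        AUC, accuracy/sensitivity/specificity) plus one discriminant row.
    discriminants : dict[str, DiscriminantResults]
    excluded : DataFrame
        Subjects left out of the analysis and why.
    """

    model: "FallRiskModel"
    rq: pd.DataFrame
    condition_comparison: pd.DataFrame
    group_comparison: pd.DataFrame
    cutoff_tables: dict = field(default_factory=dict)
    discriminants: dict = field(default_factory=dict)
    excluded: pd.DataFrame | None = None
    group_sizes: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            "Posturographic fall-risk analysis",
            "=" * 50,
            f"subjects analysed: {self.rq.shape[0]}"
            + (f" (excluded: {len(self.excluded)})" if len(self.excluded) else ""),
            "",
            "group sizes: "
            + ", ".join(f"{g}={n}" for g, n in self.group_sizes.items()),
            "",
            "Significant group differences (p < alpha):",
        ]
        sig = self.group_comparison[self.group_comparison["p"] < self.model.alpha]
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row['contrast']}: {row['variable']}  "
                    f"p={row['p']:.3f} ({row['test']})"
                )
        else:
            lines.append("  none")
        for contrast, table in self.cutoff_tables.items():
            lines.append("")
            lines.append(f"Cut-off scores, {contrast}:")
            for _, r in table.iterrows():
                auc = f" AUC={r['auc']:.3f}" if np.isfinite(r["auc"]) else ""
                lines.append(
                    f"  {r['method']:<12} {r['variable']:<12} "
                    f"cut-off={r['threshold']:.3f} ({r['direction']}){auc}  "
                    f"acc={r['accuracy']:.1f}% sens={r['sensitivity']:.1f}% "
                    f"spec={r['specificity']:.1f}%"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.model.alpha,
            "min_sensitivity": self.model.min_sensitivity,
            "group_sizes": {k: int(v) for k, v in self.group_sizes.items()},
            "condition_comparison": self.condition_comparison.to_dict("records"),
            "group_comparison": self.group_comparison.to_dict("records"),
            "cutoffs": {
                contrast: table.to_dict("records")
                for contrast, table in self.cutoff_tables.items()
            },
            "discriminants": {
                contrast: {
                    "variables": list(d.variables),
                    "intercept": d.intercept,
                    "coef": d.coef.tolist(),
                    "centroids": [d.centroid_nonfaller, d.centroid_faller],
                    "cutoff": d.cutoff,
                    "direction": d.direction,
                }
                for contrast, d in self.discriminants.items()
            },
            "excluded": self.excluded.to_dict("records"),
        }

    def save(self, outdir) -> None:
        """Write the report bundle (CSV tables + JSON summary) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.cohort.metrics_eo.to_csv(outdir / "metrics_eo.csv")
        self.model.cohort.metrics_ec.to_csv(outdir / "metrics_ec.csv")
        self.rq.to_csv(outdir / "romberg_quotients.csv")
        self.condition_comparison.to_csv(
            outdir / "condition_comparison.csv", index=False
        )
        self.group_comparison.to_csv(outdir / "group_comparison.csv", index=False)
        for contrast, table in self.cutoff_tables.items():
            slug = contrast.replace("/", "_vs_")
            table.to_csv(outdir / f"cutoffs_{slug}.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


class FallRiskModel:
    """Static-posturography fall-risk analysis of one cohort.

    Parameters
    ----------
    cohort : Cohort
        Metadata plus eyes-open and eyes-closed metric tables.
    alpha : float
        Significance level for normality routing, group screening and
        variable selection.
    min_sensitivity : float
        Sensitivity floor for ROC threshold selection (fraction).
    """

    def __init__(self, cohort: Cohort, alpha: float = 0.05,
                 min_sensitivity: float = 0.80):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < min_sensitivity < 1.0:
            raise ValueError("min_sensitivity must lie in (0, 1)")
        self.alpha = alpha
        self.min_sensitivity = min_sensitivity
        self.cohort, self._excluded = self._validate_cohort(cohort)

    @staticmethod
    def _validate_cohort(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
        """Drop subjects missing a condition, logging each exclusion."""
        rows = []
        keep = []
        for sid in cohort.subjects["subject_id"]:
            has_eo = sid in cohort.metrics_eo.index and not (
                cohort.metrics_eo.loc[sid, list(METRIC_NAMES)].isna().any()
            )
            has_ec = sid in cohort.metrics_ec.index and not (
                cohort.metrics_ec.loc[sid, list(METRIC_NAMES)].isna().any()
            )
            if has_eo and has_ec:
                keep.append(sid)
            else:
                reason = "missing eyes-open trial" if not has_eo else "missing eyes-closed trial"
                rows.append({"subject_id": sid, "reason": reason})
                logger.info("excluding %s: %s", sid, reason)
        excluded = pd.DataFrame(rows, columns=["subject_id", "reason"])
        if len(rows):
            mask = cohort.subjects["subject_id"].isin(keep)
            cohort = Cohort(
                subjects=cohort.subjects[mask].reset_index(drop=True),
                metrics_eo=cohort.metrics_eo.loc[keep],
                metrics_ec=cohort.metrics_ec.loc[keep],
            )
        return cohort, excluded

    @classmethod
    def from_tables(cls, subjects: pd.DataFrame, metrics_eo: pd.DataFrame,
                    metrics_ec: pd.DataFrame, **kwargs) -> "FallRiskModel":
        return cls(Cohort(subjects, metrics_eo, metrics_ec), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> FallRiskResults:
        cohort = self.cohort
        labeling = label_groups(cohort)
        rq = cohort.rq_table()

        results = FallRiskResults(
            model=self,
            rq=rq,
            condition_comparison=self._condition_comparisons(labeling),
            group_comparison=self._group_comparisons(labeling, rq),
            excluded=self._excluded,
            group_sizes=labeling.sizes(),
        )
        self._cutoff_analysis(results, labeling, rq)
        return results

    def _condition_comparisons(self, labeling: GroupLabeling) -> pd.DataFrame:
        cohort = self.cohort
        rows = []
        for group in ("PNF", "PAF", "PF", "PSF", "PMF"):
            members = labeling.members(group)
            if len(members) < 3:
                logger.warning("group %s too small for condition comparison", group)
                continue
            eo_tbl = cohort.metrics_eo.loc[members]
            ec_tbl = cohort.metrics_ec.loc[members]
            for metric in METRIC_NAMES:
                eo, ec = eo_tbl[metric].to_numpy(), ec_tbl[metric].to_numpy()
                res = paired_condition_compare(eo, ec, variable=metric,
                                               alpha=self.alpha)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pct = 100.0 * (ec - eo) / eo
                pct = pct[np.isfinite(pct)]
                rows.append(
                    {
                        "group": group,
                        "metric": metric,
                        "n": len(members),
                        "eo_mean": res.means[0],
                        "eo_sd": res.sds[0],
                        "ec_mean": res.means[1],
                        "ec_sd": res.sds[1],
                        "test": res.test,
                        "p": res.p_value,
                        "pct_increase_mean": float(pct.mean()) if pct.size else np.nan,
                        "pct_increase_sd": float(pct.std(ddof=1)) if pct.size > 1 else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def _group_comparisons(self, labeling: GroupLabeling, rq: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for faller_group, ref_group in CONTRASTS:
            fallers = labeling.members(faller_group)
            refs = labeling.members(ref_group)
            if len(fallers) < 3 or len(refs) < 3:
                logger.warning(
                    "contrast %s/%s skipped: too few subjects", faller_group, ref_group
                )
                continue
            for block in BLOCKS:
                table = _block_table(self.cohort, rq, block)
                for metric in METRIC_NAMES:
                    a = table.loc[refs, metric].dropna().to_numpy()
                    b = table.loc[fallers, metric].dropna().to_numpy()
                    if a.size < 3 or b.size < 3:
                        continue
                    res = independent_group_compare(
                        a, b, variable=f"{block} {metric}", alpha=self.alpha
                    )
                    rows.append(
                        {
                            "contrast": f"{faller_group}/{ref_group}",
                            "block": block,
                            "metric": metric,
                            "variable": res.variable,
                            "ref_mean": res.means[0],
                            "ref_sd": res.sds[0],
                            "faller_mean": res.means[1],
                            "faller_sd": res.sds[1],
                            "n_ref": res.ns[0],
                            "n_faller": res.ns[1],
                            "test": res.test,
                            "p": res.p_value,
                        }
                    )
        return pd.DataFrame(rows)

    def _cutoff_analysis(self, results: FallRiskResults,
                         labeling: GroupLabeling, rq: pd.DataFrame) -> None:
        gc = results.group_comparison
        if not len(gc):
            return
        for faller_group, ref_group in CONTRASTS:
            contrast = f"{faller_group}/{ref_group}"
            sig = gc[(gc["contrast"] == contrast) & (gc["p"] < self.alpha)]
            if not len(sig):
                logger.info("contrast %s: no significant variables; "
                            "cut-off stage skipped", contrast)
                continue
            fallers = labeling.members(faller_group)
            refs = labeling.members(ref_group)
            if len(fallers) < 2 or len(refs) < 2:
                logger.warning("contrast %s skipped: groups too small", contrast)
                continue
            subjects = refs.append(fallers)
            y = np.concatenate([np.zeros(len(refs), bool), np.ones(len(fallers), bool)])
            rows = []
            feature_frame = {}
            for _, srow in sig.iterrows():
                block, metric = srow["block"], srow["metric"]
                table = _block_table(self.cohort, rq, block)
                scores = table.loc[subjects, metric].to_numpy(dtype=float)
                name = f"{block} {metric}"
                feature_frame[name] = scores
                direction = "less" if srow["faller_mean"] < srow["ref_mean"] else "greater"
                clin = CutoffScore(
                    variables=(name,),
                    method="clinical",
                    threshold=clinical_cutoff(
                        srow["ref_mean"], srow["ref_sd"],
                        srow["faller_mean"], srow["faller_sd"],
                    ),
                    direction=direction,
                )
                roc = RocCutoff(
                    scores, y, direction=direction,
                    min_sensitivity=self.min_sensitivity, variable=name,
                ).fit()
                for rule in (clin, roc):
                    rep = classify_and_report(rule, scores, y)
                    rows.append(
                        {
                            "method": rule.method,
                            "variable": name,
                            "threshold": rule.threshold,
                            "direction": rule.direction,
                            "auc": rule.auc if rule.auc is not None else np.nan,
                            **rep.as_dict(),
                        }
                    )
            X = pd.DataFrame(feature_frame, index=subjects)
            if X.notna().all().all() and y.sum() >= 2 and (~y).sum() >= 2:
                disc = LinearDiscriminantCutoff(X, y).fit()
                rep = classify_and_report(disc, X, y)
                results.discriminants[contrast] = disc
                rows.append(
                    {
                        "method": "discriminant",
                        "variable": " + ".join(disc.variables),
                        "threshold": disc.cutoff,
                        "direction": disc.direction,
                        "auc": np.nan,
                        **rep.as_dict(),
                    }
                )
            results.cutoff_tables[contrast] = pd.DataFrame(rows)


def load_trace_cohort(
    trace_dir,
    metadata_path,
    config: TrialConfig | None = None,
) -> Cohort:
    """Build a cohort from per-trial force files plus a metadata table.

    Expects ``<trace_dir>/<subject_id>_<EO|EC>.csv`` force tables and a
    metadata CSV with the cohort columns.  Subjects whose files are missing
    get NaN metric rows and are excluded (and logged) at model construction.
    """
    trace_dir = Path(trace_dir)
    subjects = pd.read_csv(metadata_path)
    config = config or TrialConfig()
    tables = {}
    for cond in ("EO", "EC"):
        rows = {}
        for sid in subjects["subject_id"]:
            path = trace_dir / f"{sid}_{cond}.csv"
            if not path.exists():
                logger.warning("missing trace file %s", path)
                rows[sid] = pd.Series(np.nan, index=list(METRIC_NAMES))
                continue
            left, right = read_force_table(path)
            cop = preprocess_trial(left, right, config)
            rows[sid] = compute_metrics(cop).as_series()
        tables[cond] = pd.DataFrame(rows).T.rename_axis("subject_id")
    return Cohort(subjects=subjects, metrics_eo=tables["EO"], metrics_ec=tables["EC"])
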