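"""Faller-classification cut-off scores.

Three ways to place a scalar decision threshold between a "normal"
(non-faller) and a "clinical" (faller) group:

clinical cut-off score
    The SD-weighted compromise between the two group means,
    (sigma_n * mu_c + sigma_c * mu_n) / (sigma_n + sigma_c).  The group with
    the smaller spread pulls the threshold toward the other group's mean,
    which is less arbitrary than "two standard deviations from the mean".

ROC threshold at constrained sensitivity
    Sweep every threshold between consecutive sorted scores, keep candidates
    whose sensitivity meets a floor (default 80%, since missing a true faller
    costs more than a false alarm), and return the one with the best
    specificity.

linear discriminant
    Two-class Fisher discriminant with pooled within-group covariance and
    equal priors; the threshold is the midpoint of the two group centroids in
    discriminant-score space.

Every rule stores its direction explicitly ("greater": faller iff score
strictly above the threshold; "less": faller iff strictly below); boundary
equality is always classified non-faller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CutoffScore",
    "PerformanceReport",
    "CollinearityError",
    "clinical_cutoff",
    "roc_auc",
    "RocCutoff",
    "LinearDiscriminantCutoff",
    "DiscriminantResults",
    "classify_and_report",
]

DIRECTIONS = ("less", "greater")


class CollinearityError(ValueError):
    """Pooled within-group covariance is singular; names offending features."""

    def __init__(self, features):
        self.features = tuple(features)
        super().__init__(
            "pooled within-group covariance is singular; offending feature(s): "
            + ", ".join(map(str, self.features))
        )


@dataclass(frozen=True)
class CutoffScore:
    """A single-variable decision threshold with explicit direction."""

    variables: tuple[str, ...]
    method: str  # clinical | roc | discriminant
    threshold: float
    direction: str  # faller if strictly "less" / "greater" than threshold
    auc: float | None = None

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.auc is not None and not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")

    def classify(self, scores) -> np.ndarray:
        """Boolean faller predictions; equality with the threshold -> non-faller."""
        s = np.asarray(scores, dtype=float)
        if self.direction == "greater":
            return s > self.threshold
        return s < self.threshold


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and the derived percentages of a classification rule."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """Percent of all subjects correctly classified."""
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """Percent of true fallers classified faller."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """Percent of true non-fallers classified non-faller."""
        return 100.0 * self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def clinical_cutoff(mu_n: float, sd_n: float, mu_c: float, sd_c: float) -> float:
    """Clinical cut-off score between a normal and a clinical group.

    Returns ``(sd_n * mu_c + sd_c * mu_n) / (sd_n + sd_c)``, which lies
    weakly between the two means and sits closer to the mean of the group
    with the smaller standard deviation.

    Parameters
    ----------
    mu_n, sd_n : float
        Mean and standard deviation of the normal (non-faller) group.
    mu_c, sd_c : float
        Mean and standard deviation of the clinical (faller) group.
    """
    if sd_n <= 0 or sd_c <= 0:
        raise ValueError("group standard deviations must be positive")
    return (sd_n * mu_c + sd_c * mu_n) / (sd_n + sd_c)


def _orient(scores: np.ndarray, direction: str) -> np.ndarray:
    # map to a frame where fallers are on the high side
    return scores if direction == "greater" else -scores


def _sweep_thresholds(oriented: np.ndarray) -> np.ndarray:
    """Candidate thresholds: midpoints between consecutive unique scores
    plus one sentinel below the minimum and one above the maximum."""
    u = np.unique(oriented)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def roc_auc(scores, labels, direction: str = "greater") -> float:
    """Area under the ROC curve from the full threshold sweep.

    Oriented so that AUC > 0.5 means fallers tend to lie on the faller side
    of the stated direction.  Equals the proportion of (faller, non-faller)
    pairs ranked concordantly, ties counted one half.
    """
    s = _orient(np.asarray(scores, dtype=float), direction)
    y = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute an ROC curve")
    thresholds = _sweep_thresholds(s)[::-1]  # descending FPR order
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = [(s[y] > t).sum() / n_pos for t in thresholds]
    fpr = [(s[~y] > t).sum() / n_neg for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


class RocCutoff:
    """ROC threshold selection at a sensitivity floor.

    Parameters
    ----------
    scores : array_like
        Per-subject values of the candidate screening variable.
    labels : array_like of bool
        True for fallers.
    direction : {"greater", "less"}
        Side of the threshold on which fallers are classified.
    min_sensitivity : float
        Sensitivity floor the selected threshold must reach (fraction).
    """

    def __init__(self, scores, labels, direction: str = "greater",
                 min_sensitivity: float = 0.80, variable: str = "score"):
        self.scores = np.asarray(scores, dtype=float)
        self.labels = np.asarray(labels, dtype=bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.labels.all() or not self.labels.any():
            raise ValueError("both classes must be present")
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 < min_sensitivity < 1.0:
            raise ValueError("min_sensitivity must lie in (0, 1)")
        self.direction = direction
        self.min_sensitivity = min_sensitivity
        self.variable = variable

    def fit(self) -> CutoffScore:
        """Sweep thresholds, enforce the sensitivity floor, maximise specificity.

        Ties in specificity break toward the threshold closest to the faller
        group (the most conservative admissible cut).
        """
        s = _orient(self.scores, self.direction)
        y = self.labels
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        best = None  # (specificity, oriented threshold)
        for t in _sweep_thresholds(s):
            sens = (s[y] > t).sum() / n_pos
            if sens < self.min_sensitivity:
                continue
            spec = (s[~y] <= t).sum() / n_neg
            if best is None or (spec, t) > best:
                best = (spec, t)
        # the sentinel below min(s) classifies everyone faller (sens = 1),
        # so a candidate always exists
        thr = best[1] if self.direction == "greater" else -best[1]
        return CutoffScore(
            variables=(self.variable,),
            method="roc",
            threshold=float(thr),
            direction=self.direction,
            auc=roc_auc(self.scores, self.labels, self.direction),
        )


@dataclass(frozen=True)
class DiscriminantResults:
    """Fitted two-class linear discriminant with a centroid-midpoint cut-off.

    The discriminant score of a subject is ``intercept + coef . x``; scores
    are scaled to unit pooled within-group variance and centred so the mean
    score over all training subjects is zero.  ``cutoff`` is the midpoint of
    the two group centroids and ``direction`` is always "greater" (the score
    axis is oriented toward the faller centroid).
    """

    variables: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    centroid_nonfaller: float
    centroid_faller: float
    cutoff: float
    direction: str = "greater"

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self.intercept + X @ self.coef

    def classify(self, X) -> np.ndarray:
        """Boolean faller predictions (score strictly beyond the cut-off)."""
        s = self.score(X)
        return s > self.cutoff if self.direction == "greater" else s < self.cutoff

    def summary(self) -> str:
        terms = " ".join(
            f"{c:+.3f}*{v}" for c, v in zip(self.coef, self.variables)
        )
        return (
            f"discriminant score = {self.intercept:.3f} {terms}\n"
            f"centroids: non-faller {self.centroid_nonfaller:.3f}, "
            f"faller {self.centroid_faller:.3f}\n"
            f"cut-off {self.cutoff:.3f} (faller if score {self.direction} "
            f"than cut-off)"
        )


class LinearDiscriminantCutoff:
    """Two-class Fisher linear discriminant with equal priors.

    The discriminant axis is ``w = S_w^-1 (mu_faller - mu_nonfaller)`` with
    ``S_w`` the pooled within-group covariance; coefficients are rescaled so
    the pooled within-group variance of the score is one and the intercept
    centres the training scores at zero.  The classification threshold is
    the midpoint of the two group centroids, which with equal priors is the
    equal-Mahalanobis-distance boundary.

    Parameters
    ----------
    X : array_like or DataFrame, shape (n_subjects, n_features)
    y : array_like of bool
        True for fallers; at least 2 subjects per class.
    feature_names : sequence of str, optional
        Taken from DataFrame columns when available.
    """

    def __init__(self, X, y, feature_names=None):
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        self.y = np.asarray(y, dtype=bool)
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must align with the rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if self.y.sum() < 2 or (~self.y).sum() < 2:
            raise ValueError("need at least 2 subjects per class")
        self.feature_names = tuple(
            feature_names
            if feature_names is not None
            else (f"x{i}" for i in range(self.X.shape[1]))
        )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must match the number of columns")

    def _pooled_cov(self) -> np.ndarray:
        X0, X1 = self.X[~self.y], self.X[self.y]
        n0, n1 = len(X0), len(X1)
        s0 = np.cov(X0, rowvar=False, ddof=1)
        s1 = np.cov(X1, rowvar=False, ddof=1)
        return ((n0 - 1) * np.atleast_2d(s0) + (n1 - 1) * np.atleast_2d(s1)) / (
            n0 + n1 - 2
        )

    def fit(self) -> DiscriminantResults:
        sw = self._pooled_cov()
        if np.linalg.cond(sw) > 1e12:
            # name the features loading on the degenerate direction
            eigval, eigvec = np.linalg.eigh(sw)
            v = np.abs(eigvec[:, 0])
            bad = [n for n, w in zip(self.feature_names, v) if w > 0.1]
            raise CollinearityError(bad or self.feature_names)
        mu0 = self.X[~self.y].mean(axis=0)
        mu1 = self.X[self.y].mean(axis=0)
        w = np.linalg.solve(sw, mu1 - mu0)
        w = w / np.sqrt(w @ sw @ w)  # unit pooled within-group score variance
        intercept = -float(self.X.mean(axis=0) @ w)  # grand-mean score = 0
        scores = intercept + self.X @ w
        c0 = float(scores[~self.y].mean())
        c1 = float(scores[self.y].mean())
        return DiscriminantResults(
            variables=self.feature_names,
            intercept=intercept,
            coef=w,
            centroid_nonfaller=c0,
            centroid_faller=c1,
            cutoff=(c0 + c1) / 2.0,
            direction="greater",  # w points from mu0 toward mu1, so c1 > c0
        )


def classify_and_report(rule, data, labels) -> PerformanceReport:
    """Apply a cut-off rule and tabulate its confusion-matrix performance.

    ``rule`` is a :class:`CutoffScore` (``data``: 1-D scores) or a
    :class:`DiscriminantResults` (``data``: 2-D feature matrix).  Boundary
    equality classifies non-faller.  Missing feature values raise with the
    offending subject indices listed.
    """
    y = np.asarray(labels, dtype=bool)
    arr = np.asarray(
        data.to_numpy(dtype=float) if isinstance(data, (pd.DataFrame, pd.Series)) else data,
        dtype=float,
    )
    if arr.shape[0] != y.size:
        raise ValueError("data and labels must be aligned")
    bad = np.flatnonzero(~np.all(np.isfinite(np.atleast_2d(arr.T).T), axis=-1)
                         if arr.ndim > 1 else ~np.isfinite(arr))
    if bad.size:
        raise ValueError(f"missing feature values for subjects at rows {bad.tolist()}")
    pred = rule.classify(arr)
    return PerformanceReport(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )
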