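"""Synthetic cohorts and sway-trace simulation.

No public recording of the reference cohort exists, so every pipeline stage
is exercised on synthetic data with the cohort's statistical structure:

metric-level sampling (default, directly calibrated)
    Per-subject eyes-open and eyes-closed metric vectors drawn from
    group-conditional truncated-normal distributions with the profile means
    and SDs of :mod:`posturofall.profiles`, a configurable positive
    inter-metric correlation, and the sway-metric-set invariants enforced by
    rejection.  Romberg Quotients are computed from the sampled EO/EC pairs;
    an override sampler draws RQ values directly for cut-off calibration.

trace-level simulation (end-to-end plumbing, not physiological)
    A mean-reverting Gaussian (discrete Ornstein-Uhlenbeck) process per axis
    generates CoP trajectories; eyes closed inflates the diffusion scale.
    Traces can be rendered back into dual-board corner forces so the whole
    force -> CoP -> metrics pipeline runs on files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boards import BoardForceTrace, BoardGeometry, CoPTrace
from .cohort import Cohort
from .metrics import METRIC_NAMES
from .profiles import DEMOGRAPHICS, RQ_PROFILES, SWAY_PROFILES

__all__ = [
    "CohortConfig",
    "sample_metrics_cohort",
    "sample_rq_groups",
    "SwayProcessParams",
    "simulate_trace",
    "calibrate_process",
    "CalibrationReport",
    "trace_to_forces",
]

#: (category, n, retro falls, prospective falls, sway profile, demographics row)
#: Fine-grained composition of the reference cohort: prospective groups are
#: sampled at their own profiles; retrospective fallers (excluded from the
#: prospective tables) reuse the non-faller profile; one retrospective
#: non-faller is lost to follow-up (prospective count missing).
DEFAULT_COMPOSITION = (
    ("PNF", 47, 0, 0.0, "PNF", "PNF"),
    ("PSF", 22, 0, 1.0, "PSF", "PSF"),
    ("PMF", 6, 0, 2.0, "PMF", "PMF"),
    ("RF_faller", 14, 1, 1.0, "PAF", "RF"),
    ("RF_nonfaller", 10, 1, 0.0, "PNF", "RF"),
    ("RNF_lost", 1, 0, float("nan"), "PNF", "RNF"),
)

@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the metric-level cohort sampler."""

    seed: int
    composition: tuple = DEFAULT_COMPOSITION
    correlation: float = 0.5
    sway_profiles: dict = field(default_factory=lambda: SWAY_PROFILES)

    def __post_init__(self):
        if not 0.0 <= self.correlation <= 0.9:
            raise ValueError("inter-metric correlation must lie in [0, 0.9]")


def _profile_mean_sd(profile: dict) -> tuple[np.ndarray, np.ndarray]:
    mean = np.array([profile[m][0] for m in METRIC_NAMES])
    sd = np.array([profile[m][1] for m in METRIC_NAMES])
    return mean, sd


def _truncnorm_draw(
    rng: np.random.Generator,
    mu: float,
    sd: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Exact truncated-normal draws on per-row intervals (inverse CDF)."""
    from scipy import stats as sps

    if sd == 0:
        return np.clip(np.full_like(np.asarray(lo, float), mu), lo, hi)
    a = sps.norm.cdf((lo - mu) / sd)
    b = sps.norm.cdf((hi - mu) / sd)
    u = rng.uniform(a, np.maximum(b, a + 1e-12))
    return mu + sd * sps.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def _sample_trial_pairs(
    rng: np.random.Generator,
    profile_eo: dict,
    profile_ec: dict,
    n: int,
    correlation: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n valid (EO, EC) 7-metric vectors from the group profile.

    The 14-dimensional draw uses an equicorrelated Gaussian (the same
    positive correlation between every metric pair, within and across
    conditions, reflecting that steadier subjects are steadier throughout).
    Metric-set invariants are enforced by resampling only the violating
    component from its truncated-normal marginal on the feasible interval
    (non-negativity for ranges and velocities, [0, range] for RMS, the
    triangle-inequality band for the resultant velocity), so unconstrained
    marginals keep exactly the profile's mean and SD.  The resultant
    velocity lives on a narrow subject-specific band and is therefore
    usually conditionally drawn; its group mean drifts a few percent from
    the profile value.  A warning is issued when one of the other
    components needs constrained resampling in over a quarter of draws
    (the invariants are then improbable under that profile).
    """
    mean = np.concatenate(
        [_profile_mean_sd(profile_eo)[0], _profile_mean_sd(profile_ec)[0]]
    )
    sd = np.concatenate(
        [_profile_mean_sd(profile_eo)[1], _profile_mean_sd(profile_ec)[1]]
    )
    d = mean.size
    corr = np.full((d, d), correlation)
    np.fill_diagonal(corr, 1.0)
    # factor the correlation (positive definite for correlation < 1) and
    # scale afterwards so zero-SD components stay exactly constant
    chol = np.linalg.cholesky(corr)
    v = mean + (rng.standard_normal((n, d)) @ chol.T) * sd

    worst_frac = 0.0
    inf = np.inf
    for off in (0, 7):
        # ranges and per-axis velocities: non-negative
        for j in (off + 0, off + 1, off + 4, off + 5):
            bad = v[:, j] < 0
            worst_frac = max(worst_frac, bad.mean())
            if bad.any():
                v[bad, j] = _truncnorm_draw(
                    rng, mean[j], sd[j], np.zeros(bad.sum()), np.full(bad.sum(), inf)
                )
        # RMS: within [0, range] of its axis
        for j, jr in ((off + 2, off + 0), (off + 3, off + 1)):
            bad = (v[:, j] < 0) | (v[:, j] > v[:, jr])
            worst_frac = max(worst_frac, bad.mean())
            if bad.any():
                v[bad, j] = _truncnorm_draw(
                    rng, mean[j], sd[j], np.zeros(bad.sum()), v[bad, jr]
                )
        # resultant velocity: triangle-inequality band
        j = off + 6
        lo = np.maximum(v[:, off + 4], v[:, off + 5])
        hi = v[:, off + 4] + v[:, off + 5]
        bad = (v[:, j] < lo) | (v[:, j] > hi)
        if bad.any():
            v[bad, j] = _truncnorm_draw(rng, mean[j], sd[j], lo[bad], hi[bad])
    if n >= 100 and worst_frac > 0.25:
        warnings.warn(
            "profile and metric-set invariants conflict: a component needed "
            f"constrained resampling in {100 * worst_frac:.0f}% of draws; "
            "group-level statistics will deviate from the profile",
            stacklevel=2,
        )
    return v[:, :7], v[:, 7:]


def sample_metrics_cohort(config: CohortConfig) -> Cohort:
    """Generate a metric-level synthetic cohort (no traces).

    Deterministic under a fixed seed.  Subjects are drawn category by
    category per ``config.composition``; demographics come from the matching
    group's normative statistics and are metadata only (they do not shape
    the sway draws).
    """
    rng = np.random.default_rng(config.seed)
    meta_rows, eo_rows, ec_rows, ids = [], [], [], []
    counter = 0
    for category, n, retro, pro, profile_key, demo_key in config.composition:
        prof = config.sway_profiles[profile_key]
        eo, ec = _sample_trial_pairs(
            rng, prof["EO"], prof["EC"], n, config.correlation
        )
        demo = DEMOGRAPHICS.loc[demo_key]
        n_male = int(round(n * demo["male"] / demo["n"]))
        for i in range(n):
            sid = f"S{counter:03d}"
            counter += 1
            ids.append(sid)
            meta_rows.append(
                {
                    "subject_id": sid,
                    "category": category,
                    "sex": "M" if i < n_male else "F",
                    "age": float(rng.normal(demo["age_mean"], demo["age_sd"])),
                    "height": float(
                        rng.normal(demo["height_mean"], demo["height_sd"])
                    ),
                    "weight": float(
                        max(rng.normal(demo["weight_mean"], demo["weight_sd"]), 35.0)
                    ),
                    "retro_falls": int(retro),
                    "pro_falls": pro,
                }
            )
        eo_rows.append(eo)
        ec_rows.append(ec)
    subjects = pd.DataFrame(meta_rows)
    idx = pd.Index(ids, name="subject_id")
    metrics_eo = pd.DataFrame(np.vstack(eo_rows), index=idx, columns=METRIC_NAMES)
    metrics_ec = pd.DataFrame(np.vstack(ec_rows), index=idx, columns=METRIC_NAMES)
    return Cohort(subjects=subjects, metrics_eo=metrics_eo, metrics_ec=metrics_ec)


def sample_rq_groups(
    groups: dict[str, int],
    seed: int,
    correlation: float = 0.5,
    rq_profiles: dict | None = None,
) -> pd.DataFrame:
    """Draw per-subject Romberg Quotient vectors directly per group.

    Override sampler for calibrating cut-off methods against known generating
    parameters: RQ vectors come straight from the group RQ profiles
    (equicorrelated normal truncated at zero by rejection), bypassing the
    mean-of-ratios drift of computing RQ from sampled EO/EC pairs.

    Returns a frame with a ``group`` column and one column per metric.
    """
    rq_profiles = rq_profiles if rq_profiles is not None else RQ_PROFILES
    rng = np.random.default_rng(seed)
    frames = []
    d = len(METRIC_NAMES)
    corr = np.full((d, d), correlation)
    np.fill_diagonal(corr, 1.0)
    for group, n in groups.items():
        mean, sd = _profile_mean_sd(rq_profiles[group])
        chol = np.linalg.cholesky(corr)
        v = mean + (rng.standard_normal((n, d)) @ chol.T) * sd
        # enforce positivity by redrawing only the offending component, so
        # each marginal stays an exact zero-truncated normal
        for j in range(d):
            bad = v[:, j] <= 0
            if bad.any():
                v[bad, j] = _truncnorm_draw(
                    rng, mean[j], sd[j], np.zeros(bad.sum()), np.full(bad.sum(), np.inf)
                )
        df = pd.DataFrame(v, columns=METRIC_NAMES)
        df.insert(0, "group", group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# trace-level simulation


@dataclass(frozen=True)
class SwayProcessParams:
    """Parameters of the per-axis mean-reverting sway process.

    ``sigma_*`` are diffusion scales (mm/sqrt(s)); ``theta_*`` mean-reversion
    rates (1/s); ``ec_mult_*`` the eyes-closed diffusion multipliers.
    """

    sigma_ap: float
    sigma_ml: float
    theta_ap: float
    theta_ml: float
    ec_mult_ap: float = 1.0
    ec_mult_ml: float = 1.0
    fs: float = 100.0
    duration: float = 30.0

    def __post_init__(self):
        if min(self.sigma_ap, self.sigma_ml) < 0:
            raise ValueError("diffusion scales must be non-negative")
        if min(self.theta_ap, self.theta_ml) < 0:
            raise ValueError("mean-reversion rates must be non-negative")
        if min(self.ec_mult_ap, self.ec_mult_ml) <= 0:
            raise ValueError("eyes-closed multipliers must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    def for_condition(self, condition: str) -> "SwayProcessParams":
        if condition == "EO":
            return self
        if condition == "EC":
            return replace(
                self,
                sigma_ap=self.sigma_ap * self.ec_mult_ap,
                sigma_ml=self.sigma_ml * self.ec_mult_ml,
                ec_mult_ap=1.0,
                ec_mult_ml=1.0,
            )
        raise ValueError("condition must be 'EO' or 'EC'")


def _ou_paths(
    rng: np.random.Generator,
    sigma: float,
    theta: float,
    n_samples: int,
    dt: float,
    n_paths: int,
) -> np.ndarray:
    """Exact-discretisation OU sample paths, stationary start, shape (R, N)."""
    if sigma == 0.0:
        return np.zeros((n_paths, n_samples))
    if theta > 0:
        rho = np.exp(-theta * dt)
        s_stat = sigma / np.sqrt(2.0 * theta)
        step_sd = s_stat * np.sqrt(1.0 - rho * rho)
        x0 = rng.standard_normal(n_paths) * s_stat
    else:  # random-walk limit
        rho = 1.0
        step_sd = sigma * np.sqrt(dt)
        x0 = np.zeros(n_paths)
    from scipy.signal import lfilter

    eps = rng.standard_normal((n_paths, n_samples - 1)) * step_sd
    # AR(1) recursion x_i = rho x_{i-1} + eps_i via a linear filter
    tail, _ = lfilter(
        [1.0], [1.0, -rho], eps, axis=1, zi=(rho * x0)[:, None]
    )
    return np.concatenate([x0[:, None], tail], axis=1)


def simulate_trace(
    params: SwayProcessParams, seed: int, condition: str = "EO"
) -> CoPTrace:
    """Simulate one quiet-stance CoP trace (independent AP and ML axes)."""
    p = params.for_condition(condition)
    rng = np.random.default_rng(seed)
    n = int(round(p.duration * p.fs))
    dt = 1.0 / p.fs
    ap = _ou_paths(rng, p.sigma_ap, p.theta_ap, n, dt, 1)[0]
    ml = _ou_paths(rng, p.sigma_ml, p.theta_ml, n, dt, 1)[0]
    return CoPTrace(ap=ap, ml=ml, fs=p.fs)


def _ou_step_sd(sigma: float, theta: float, dt: float) -> float:
    if theta > 0:
        return sigma / np.sqrt(2 * theta) * np.sqrt(2 * (1 - np.exp(-theta * dt)))
    return sigma * np.sqrt(dt)


def _ou_expected_velocity(sigma: float, theta: float, dt: float) -> float:
    # mean |increment| of a stationary Gaussian process, per unit time
    return _ou_step_sd(sigma, theta, dt) * np.sqrt(2.0 / np.pi) / dt


def _ou_expected_trial_rms(
    sigma: float, theta: float, dt: float, n_samples: int
) -> float:
    """Expected RMS about the within-trial mean for a stationary OU path."""
    if sigma == 0:
        return 0.0
    if theta == 0:
        # Brownian about its path mean: E[var] ~ sigma^2 * T / 6
        return sigma * np.sqrt(n_samples * dt / 6.0)
    s2 = sigma**2 / (2 * theta)
    k = np.arange(1, n_samples)
    rho_k = np.exp(-theta * dt * k)
    mean_var = s2 * (1.0 - (n_samples + 2.0 * np.sum((n_samples - k) * rho_k)) / n_samples**2)
    return float(np.sqrt(max(mean_var, 0.0)))


@dataclass(frozen=True)
class CalibrationReport:
    """Targets versus model-predicted means for a process calibration."""

    table: pd.DataFrame  # columns: axis, condition, metric, target, achieved
    tolerance: float

    @property
    def success(self) -> bool:
        rel = np.abs(self.table["achieved"] / self.table["target"] - 1.0)
        return bool((rel <= self.tolerance).all())

    def failures(self) -> pd.DataFrame:
        rel = np.abs(self.table["achieved"] / self.table["target"] - 1.0)
        return self.table[rel > self.tolerance]


def calibrate_process(
    profile: dict,
    fs: float = 100.0,
    duration: float = 30.0,
    tolerance: float = 0.15,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[SwayProcessParams, CalibrationReport]:
    """Fit sway-process parameters to a group profile's velocity and RMS.

    Per axis, the diffusion scale is pinned by the eyes-open mean velocity
    (the mean absolute increment of the process is known in closed form),
    the eyes-closed multiplier by the EC/EO velocity ratio, and the
    mean-reversion rate by a grid search minimising joint log-error of the
    within-trial RMS under both conditions.  Achieved values in the report
    are means over seeded simulated replicates.

    A single-timescale process cannot always reach both targets; the report
    flags any metric off by more than ``tolerance`` (velocities are matched
    essentially exactly, amplitude shortfalls are the honest residual).
    """
    dt = 1.0 / fs
    n = int(round(duration * fs))
    eo, ec = profile["EO"], profile["EC"]
    theta_grid = np.geomspace(1e-3, 30.0, 200)

    def fit_axis(axis: str) -> tuple[float, float, float]:
        v_eo, v_ec = eo[f"vel_{axis}"][0], ec[f"vel_{axis}"][0]
        r_eo, r_ec = eo[f"rms_{axis}"][0], ec[f"rms_{axis}"][0]
        best = None
        for theta in theta_grid:
            # sigma giving the target mean velocity at this reversion rate
            d_eo = v_eo * np.sqrt(np.pi / 2.0) * dt
            scale = np.sqrt(theta / (1.0 - np.exp(-theta * dt)))
            sigma_eo = d_eo / np.sqrt(dt) if theta == 0 else d_eo * scale
            sigma_ec = sigma_eo * (v_ec / v_eo)
            err = np.log(
                _ou_expected_trial_rms(sigma_eo, theta, dt, n) / r_eo
            ) ** 2 + np.log(
                _ou_expected_trial_rms(sigma_ec, theta, dt, n) / r_ec
            ) ** 2
            if best is None or err < best[0]:
                best = (err, theta, sigma_eo, sigma_ec)
        _, theta, sigma_eo, sigma_ec = best
        return sigma_eo, theta, sigma_ec / sigma_eo

    sigma_ap, theta_ap, mult_ap = fit_axis("ap")
    sigma_ml, theta_ml, mult_ml = fit_axis("ml")
    params = SwayProcessParams(
        sigma_ap=sigma_ap,
        sigma_ml=sigma_ml,
        theta_ap=theta_ap,
        theta_ml=theta_ml,
        ec_mult_ap=mult_ap,
        ec_mult_ml=mult_ml,
        fs=fs,
        duration=duration,
    )

    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("EO", "EC"):
        p = params.for_condition(condition)
        prof = profile[condition]
        for axis, sigma, theta in (
            ("ap", p.sigma_ap, p.theta_ap),
            ("ml", p.sigma_ml, p.theta_ml),
        ):
            paths = _ou_paths(rng, sigma, theta, n, dt, n_replicates)
            rms = np.sqrt(np.mean((paths - paths.mean(axis=1, keepdims=True)) ** 2, axis=1))
            vel = np.sum(np.abs(np.diff(paths, axis=1)), axis=1) / ((n - 1) * dt)
            rows.append((axis, condition, "vel", prof[f"vel_{axis}"][0], vel.mean()))
            rows.append((axis, condition, "rms", prof[f"rms_{axis}"][0], rms.mean()))
    report = CalibrationReport(
        table=pd.DataFrame(
            rows, columns=["axis", "condition", "metric", "target", "achieved"]
        ),
        tolerance=tolerance,
    )
    return params, report


def trace_to_forces(
    cop: CoPTrace,
    weight_n: float,
    left_geom: BoardGeometry,
    right_geom: BoardGeometry,
) -> tuple[BoardForceTrace, BoardForceTrace]:
    """Render a net CoP trace into dual-board corner forces.

    Both boards keep their local CoP at (ap, 0); the net ML coordinate is
    produced by redistributing vertical force between the boards, which is
    how quiet-stance ML sway actually arises.  The synthesis inverts the
    processing pipeline exactly when filtering is disabled.
    """
    off_l, off_r = left_geom.origin_offset_ml, right_geom.origin_offset_ml
    if off_r <= off_l:
        raise ValueError("right board must sit lateral-positive of the left board")
    # weights solving wl*off_l + wr*off_r = W*ml, wl + wr = W
    frac_r = (cop.ml - off_l) / (off_r - off_l)
    if np.any((frac_r < 0) | (frac_r > 1)):
        raise ValueError("net ML trajectory leaves the span of the two boards")
    w_r = weight_n * frac_r
    w_l = weight_n - w_r

    def corner_forces(total: np.ndarray, geom: BoardGeometry) -> np.ndarray:
        a = 2.0 * cop.ap / geom.length_ap  # local AP, both boards alike
        if np.any(np.abs(a) > 1):
            raise ValueError("AP trajectory leaves the board surface")
        quarter = total / 4.0
        tl = quarter * (1 + a)
        tr = quarter * (1 + a)
        bl = quarter * (1 - a)
        br = quarter * (1 - a)
        return np.column_stack([tl, tr, bl, br])

    left = BoardForceTrace(forces=corner_forces(w_l, left_geom), fs=cop.fs)
    right = BoardForceTrace(forces=corner_forces(w_r, right_geom), fs=cop.fs)
    return left, right
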