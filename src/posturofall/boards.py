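"""Dual balance-board signal processing.

A consumer balance board reports vertical force at four corner sensors
(top-left, top-right, bottom-left, bottom-right, with "top" = anterior and
"right" = lateral-positive).  The center of pressure (CoP) of one board is the
moment-balance solution of the four forces over the sensor rectangle; two
boards, one under each foot, combine into a net CoP by force-weighted
averaging after each board is shifted to its position in the stance.

Axis convention: AP positive anterior, ML positive to the subject's right,
units mm throughout.  Raw force channels are smoothed with a centered moving
average before CoP computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BoardGeometry",
    "BoardForceTrace",
    "CoPTrace",
    "DegenerateLoadError",
    "moving_average",
    "board_cop",
    "combine_boards",
    "preprocess_trial",
    "read_force_table",
    "write_force_table",
    "TrialConfig",
]

#: Default sensor spacing of the supported consumer balance board, mm.
DEFAULT_LENGTH_AP = 433.0
DEFAULT_WIDTH_ML = 228.0

#: Minimum admissible per-sample total vertical force, N.
DEFAULT_FORCE_FLOOR = 1.0

CHANNELS = ("TL", "TR", "BL", "BR")
FORCE_COLUMNS = tuple(f"{side}_{ch}" for side in ("L", "R") for ch in CHANNELS)


class DegenerateLoadError(ValueError):
    """Total vertical force at or below the force floor at some sample."""

    def __init__(self, sample_index: int, total_force: float):
        self.sample_index = int(sample_index)
        self.total_force = float(total_force)
        super().__init__(
            f"total vertical force {total_force:.3g} N <= force floor at "
            f"sample {sample_index}; CoP is undefined under near-zero load"
        )


@dataclass(frozen=True)
class BoardGeometry:
    """Sensor layout of one board and its placement in the stance.

    Parameters
    ----------
    length_ap : float
        Sensor spacing along the anterior-posterior axis, mm.
    width_ml : float
        Sensor spacing along the medial-lateral axis, mm.
    origin_offset_ml : float
        Lateral displacement of this board's center from the combined-stance
        midline, mm (negative for the left board, positive for the right).
    """

    length_ap: float = DEFAULT_LENGTH_AP
    width_ml: float = DEFAULT_WIDTH_ML
    origin_offset_ml: float = 0.0

    def __post_init__(self):
        if self.length_ap <= 0 or self.width_ml <= 0:
            raise ValueError("board sensor spacings must be positive")

    def with_offset(self, origin_offset_ml: float) -> "BoardGeometry":
        return replace(self, origin_offset_ml=float(origin_offset_ml))


@dataclass
class BoardForceTrace:
    """Uniformly sampled 4-channel vertical force record for one board.

    ``forces`` has shape (n_samples, 4), columns ordered TL, TR, BL, BR, in
    newtons.
    """

    forces: np.ndarray
    fs: float

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 4:
            raise ValueError("forces must have shape (n_samples, 4)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("forces must be finite")
        if np.any(self.total_force() < 0):
            raise ValueError("per-sample total force must be >= 0")

    def total_force(self) -> np.ndarray:
        return self.forces.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CoPTrace:
    """Planar CoP trajectory: AP and ML coordinates in mm at fixed rate."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float

    def __post_init__(self):
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if self.ap.ndim != 1 or self.ml.ndim != 1 or self.ap.size != self.ml.size:
            raise ValueError("ap and ml must be 1-D arrays of equal length")
        if self.ap.size < 2:
            raise ValueError("CoP trace needs at least 2 samples")
        if not (np.all(np.isfinite(self.ap)) and np.all(np.isfinite(self.ml))):
            raise ValueError("CoP coordinates must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.ap.size

    @property
    def duration(self) -> float:
        """Trial duration spanned by the samples, (N-1)/fs seconds."""
        return (self.n_samples - 1) / self.fs


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the boundaries.

    Each output point is the mean of the ``window`` samples centered on it;
    near the edges the window is truncated symmetrically so the output has
    the same length as the input and no phase shift.

    Parameters
    ----------
    series : array_like, 1-D
    window : int
        Odd window length, 1 <= window <= len(series).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    window = int(window)
    if window < 1 or window > x.size:
        raise ValueError("window must satisfy 1 <= window <= len(series)")
    if window % 2 == 0:
        raise ValueError("window must be odd for a centered filter")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    # symmetric truncation: half-width shrinks to the distance to the edge
    h = np.minimum(half, np.minimum(idx, x.size - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def board_cop(
    trace: BoardForceTrace,
    geometry: BoardGeometry,
    force_floor: float = DEFAULT_FORCE_FLOOR,
) -> CoPTrace:
    """CoP of one board from its four corner forces by moment balance.

    AP = (L/2)·[(F_TL + F_TR) − (F_BL + F_BR)] / F_total and
    ML = (W/2)·[(F_TR + F_BR) − (F_TL + F_BL)] / F_total per sample, where L
    and W are the sensor spacings.  The result always lies inside the sensor
    rectangle.  ML is in the board's local frame (``origin_offset_ml`` is
    applied only when boards are combined).

    Raises
    ------
    DegenerateLoadError
        If any sample's total force is at or below ``force_floor``.
    """
    f = trace.forces
    total = trace.total_force()
    bad = np.flatnonzero(total <= force_floor)
    if bad.size:
        raise DegenerateLoadError(bad[0], total[bad[0]])
    tl, tr, bl, br = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    ap = (geometry.length_ap / 2.0) * ((tl + tr) - (bl + br)) / total
    ml = (geometry.width_ml / 2.0) * ((tr + br) - (tl + bl)) / total
    return CoPTrace(ap=ap, ml=ml, fs=trace.fs)


def combine_boards(
    left: CoPTrace,
    left_total_force: np.ndarray,
    right: CoPTrace,
    right_total_force: np.ndarray,
    left_geom: BoardGeometry,
    right_geom: BoardGeometry,
    force_floor: float = DEFAULT_FORCE_FLOOR,
) -> CoPTrace:
    """Net CoP of a two-board stance by instantaneous force weighting.

    Each board's local ML coordinate is shifted by its ``origin_offset_ml``
    into the stance frame; the net CoP is the per-sample weighted average of
    the two board CoPs with weights equal to each board's share of the
    combined vertical force.  This equals the single-plate CoP of all eight
    sensors placed at their stance-frame coordinates.
    """
    wl = np.asarray(left_total_force, dtype=float)
    wr = np.asarray(right_total_force, dtype=float)
    n = left.ap.size
    if not (right.ap.size == wl.size == wr.size == n):
        raise ValueError("combine_boards inputs must have equal lengths")
    if left.fs != right.fs:
        raise ValueError("boards must share one sampling rate")
    total = wl + wr
    bad = np.flatnonzero(total <= force_floor)
    if bad.size:
        raise DegenerateLoadError(bad[0], total[bad[0]])
    ap = (wl * left.ap + wr * right.ap) / total
    ml = (
        wl * (left.ml + left_geom.origin_offset_ml)
        + wr * (right.ml + right_geom.origin_offset_ml)
    ) / total
    return CoPTrace(ap=ap, ml=ml, fs=left.fs)


@dataclass(frozen=True)
class TrialConfig:
    """Processing configuration for one dual-board trial."""

    filter_window: int = 15
    left_geometry: BoardGeometry = field(
        default_factory=lambda: BoardGeometry(
            origin_offset_ml=-DEFAULT_WIDTH_ML / 2.0
        )
    )
    right_geometry: BoardGeometry = field(
        default_factory=lambda: BoardGeometry(origin_offset_ml=DEFAULT_WIDTH_ML / 2.0)
    )
    force_floor: float = DEFAULT_FORCE_FLOOR
    #: Smooth raw force channels (default) rather than the combined CoP.
    filter_forces: bool = True

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("filter_window", "force_floor", "filter_forces"):
            if key in raw:
                kwargs[key] = raw[key]
        for side in ("left", "right"):
            gkey = f"{side}_geometry"
            if gkey in raw:
                kwargs[gkey] = BoardGeometry(**raw[gkey])
        return cls(**kwargs)


def preprocess_trial(
    left: BoardForceTrace,
    right: BoardForceTrace,
    config: TrialConfig | None = None,
) -> CoPTrace:
    """Raw dual-board forces -> single filtered CoP trajectory.

    Applies the moving-average filter to each of the 8 force channels, then
    per-board moment balance, then force-weighted combination.  The trace is
    not demeaned here; sway metrics demean internally.
    """
    config = config or TrialConfig()
    if left.fs != right.fs:
        raise ValueError("boards must share one sampling rate")
    if left.n_samples != right.n_samples:
        raise ValueError("boards must have equal trial lengths")

    def smooth(trace: BoardForceTrace) -> BoardForceTrace:
        if not config.filter_forces or config.filter_window == 1:
            return trace
        filt = np.column_stack(
            [moving_average(trace.forces[:, j], config.filter_window) for j in range(4)]
        )
        return BoardForceTrace(forces=filt, fs=trace.fs)

    lf, rf = smooth(left), smooth(right)
    cop_l = board_cop(lf, config.left_geometry, config.force_floor)
    cop_r = board_cop(rf, config.right_geometry, config.force_floor)
    combined = combine_boards(
        cop_l,
        lf.total_force(),
        cop_r,
        rf.total_force(),
        config.left_geometry,
        config.right_geometry,
        config.force_floor,
    )
    if config.filter_forces or config.filter_window == 1:
        return combined
    # alternative ordering: filter the combined CoP instead of the forces
    return CoPTrace(
        ap=moving_average(combined.ap, config.filter_window),
        ml=moving_average(combined.ml, config.filter_window),
        fs=combined.fs,
    )


def read_force_table(path, fs_tolerance: float = 0.01) -> tuple[BoardForceTrace, BoardForceTrace]:
    """Read a delimited force-trace file into left and right board traces.

    Expects columns ``time_s`` then ``{L,R}_{TL,TR,BL,BR}`` with a header;
    comma or tab delimited.  The sampling rate is validated from the time
    column (uniform to within ``fs_tolerance`` relative deviation).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("time_s", *FORCE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"force table {path} missing columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    dt_med = np.median(dt)
    if np.max(np.abs(dt - dt_med)) > fs_tolerance * dt_med:
        raise ValueError("time column is not uniformly sampled within tolerance")
    fs = 1.0 / dt_med
    left = BoardForceTrace(
        forces=df[[f"L_{ch}" for ch in CHANNELS]].to_numpy(dtype=float), fs=fs
    )
    right = BoardForceTrace(
        forces=df[[f"R_{ch}" for ch in CHANNELS]].to_numpy(dtype=float), fs=fs
    )
    return left, right


def write_force_table(path, left: BoardForceTrace, right: BoardForceTrace) -> None:
    """Write left/right board force traces to CSV (inverse of the reader)."""
    if left.fs != right.fs or left.n_samples != right.n_samples:
        raise ValueError("boards must match in rate and length")
    t = np.arange(left.n_samples) / left.fs
    data = {"time_s": t}
    for side, trace in (("L", left), ("R", right)):
        for j, ch in enumerate(CHANNELS):
            data[f"{side}_{ch}"] = trace.forces[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
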