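"""Replication scores, RT values, variability scores and RT dynamics.

The genome-wide replication score of a cell is the percentage of its
unmasked bins binarized as replicated — a proxy for S-phase progression.
Raw RT of a bin is the fraction of cells that replicated it (higher =
earlier).  To correct for uneven sampling of cells across S phase, the
interval RT averages the replicated fraction over overlapping
replication-score windows (35% wide, stepped by 4.33%, 16 windows over
0-100%).  The variability score 1 - |p - 0.5| / 0.5 of the corrected
fraction p peaks at bins replicated in exactly half the cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryReplicationMatrix, RTProfile


@dataclass
class IntervalGrid:
    """Overlapping replication-score intervals for sampling correction.

    Intervals are [lo, lo + window) stepped by ``step`` percent, the last
    one closed at 100 so every cell falls in at least one interval.  The
    default 35% window with 4.33% step yields 16 intervals.
    """

    window_size: float = 35.0
    step: float = 4.33
    intervals: list[tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.window_size > 100:
            raise ValueError("window_size and step must be positive, window <= 100")
        if self.intervals is None:
            n = int(np.floor((100.0 - self.window_size) / self.step + 1e-9)) + 1
            self.intervals = [
                (i * self.step, i * self.step + self.window_size) for i in range(n)
            ]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def membership(self, scores: np.ndarray) -> np.ndarray:
        """Boolean intervals x cells membership matrix (last interval closed)."""
        scores = np.asarray(scores, dtype=float)
        out = np.zeros((self.n_intervals, scores.size), dtype=bool)
        for i, (lo, hi) in enumerate(self.intervals):
            if i == self.n_intervals - 1:
                out[i] = (scores >= lo) & (scores <= max(hi, 100.0))
            else:
                out[i] = (scores >= lo) & (scores < hi)
        return out


def replication_score(states: BinaryReplicationMatrix) -> np.ndarray:
    """Per-cell percentage of unmasked bins in the replicated state."""
    observed = states.unmasked()
    n_obs = observed.sum(axis=1)
    if np.any(n_obs == 0):
        bad = [states.cell_ids[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"cells with no unmasked bins: {bad}")
    ones = ((states.states == 1) & observed).sum(axis=1)
    return 100.0 * ones / n_obs


def filter_cells_by_score(states: BinaryReplicationMatrix, lo: float = 10.0,
                          hi: float = 90.0) -> BinaryReplicationMatrix:
    """Keep mid-S cells: replication score within [lo, hi], bounds inclusive.

    Cells below 10% or above 90% carry too little contrast between
    replicated and unreplicated bins for reliable binarization.
    """
    scores = replication_score(states)
    keep = (scores >= lo) & (scores <= hi)
    if not keep.any():
        raise ValueError(
            f"no cells with replication score in [{lo}, {hi}] "
            f"(of {states.n_cells}: {np.sum(scores < lo)} below, "
            f"{np.sum(scores > hi)} above)"
        )
    return states.subset_cells(keep)


def rt_values(states: BinaryReplicationMatrix, grid: IntervalGrid | None = None,
              stage: str | None = None) -> RTProfile:
    """Raw and interval-averaged RT plus variability score per bin.

    rt_raw is the replicated fraction over all cells.  rt_interval
    averages, over the score intervals that contain at least one cell,
    the within-interval replicated fraction; empty intervals are dropped
    from the average rather than counted as zero.  Bins observed in no
    cell are NaN.
    """
    if states.n_cells == 0:
        raise ValueError("empty replication matrix")
    grid = grid or IntervalGrid()
    observed = states.unmasked()
    ones = (states.states == 1) & observed
    with np.errstate(invalid="ignore"):
        rt_raw = np.where(observed.any(axis=0),
                          ones.sum(axis=0) / np.maximum(observed.sum(axis=0), 1),
                          np.nan)
    member = grid.membership(replication_score(states))
    fracs = np.full((grid.n_intervals, states.bins.n_bins), np.nan)
    for i in range(grid.n_intervals):
        cells = member[i]
        if not cells.any():
            continue
        obs = observed[cells]
        denom = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fracs[i] = np.where(denom > 0, ones[cells].sum(axis=0) / denom, np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-empty bins
        rt_interval = np.nanmean(fracs, axis=0)
    variability = variability_score(rt_interval)
    if stage is None:
        stage_vals = states.cell_meta["stage"].unique()
        stage = str(stage_vals[0]) if len(stage_vals) == 1 else "mixed"
    return RTProfile(states.bins, rt_raw, rt_interval, variability,
                     stage=stage, n_cells=states.n_cells)


def variability_score(p: float | np.ndarray) -> np.ndarray:
    """1 - |p - 0.5| / 0.5 for replicated fraction p; 1 at p = 0.5, 0 at 0 or 1."""
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - np.abs(p - 0.5) / 0.5


CONSTANT_EARLY = "constant-early"
CONSTANT_LATE = "constant-late"
INCREASE = "increase"
SHUFFLE = "shuffle"
OTHER = "other"


def rt_dynamics(profiles: list[RTProfile], early_cut: float = 0.5,
                late_cut: float = 0.5, mid_range: tuple[float, float] = (0.4, 0.8),
                min_delta: float = 0.1) -> dict:
    """Classify each bin's RT trajectory across ordered stages.

    Classes: ``constant-early`` (RT >= early_cut at every stage and a
    stable trajectory, total change < ``min_delta``), ``constant-late``
    (likewise on the late side), ``shuffle`` (an
    early<->late switch of at least ``min_delta`` between consecutive
    stages), ``increase`` (monotone sharpening toward the extremes by at
    least ``min_delta`` overall without switching side), else ``other``.
    Also reports, per stage, the fraction of bins with intermediate RT
    (within ``mid_range``).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 stages")
    base = profiles[0].bins
    for p in profiles[1:]:
        if not p.bins.same_coords(base):
            raise ValueError("profiles must share a bin grid")
    rt = np.vstack([p.rt_interval for p in profiles])  # stages x bins
    n_stages, n_bins = rt.shape
    classes = np.full(n_bins, OTHER, dtype=object)
    valid = np.isfinite(rt).all(axis=0)
    early = rt >= early_cut
    late = rt <= late_cut
    stable = (rt.max(axis=0) - rt.min(axis=0)) < min_delta
    classes[valid & stable & early.all(axis=0)] = CONSTANT_EARLY
    classes[valid & stable & late.all(axis=0) & ~early.all(axis=0)] = CONSTANT_LATE
    delta = np.diff(rt, axis=0)
    switch = ((early[:-1] & late[1:] & (delta <= -min_delta))
              | (late[:-1] & early[1:] & (delta >= min_delta)))
    is_shuffle = valid & switch.any(axis=0) & (classes == OTHER)
    classes[is_shuffle] = SHUFFLE
    # monotone sharpening: distance from 0.5 grows by >= min_delta overall
    sharp0 = np.abs(rt[0] - 0.5)
    sharpT = np.abs(rt[-1] - 0.5)
    sharp_steps = np.diff(np.abs(rt - 0.5), axis=0)
    is_increase = (valid & (classes == OTHER)
                   & (sharpT - sharp0 >= min_delta)
                   & (sharp_steps >= -1e-9).all(axis=0))
    classes[is_increase] = INCREASE
    mid_fraction = np.array([
        np.mean((p.rt_interval >= mid_range[0]) & (p.rt_interval <= mid_range[1])
                & np.isfinite(p.rt_interval))
        for p in profiles
    ])
    return {"classes": classes, "mid_fraction": mid_fraction,
            "stages": [p.stage for p in profiles]}
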