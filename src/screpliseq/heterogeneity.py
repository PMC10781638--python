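"""Per-bin sigmoid model of replication across S-phase progression.

For each genomic bin, the percentage of cells that replicated it (y) is
related to S-phase progression measured by the replication-score interval
(x) through

    y = 100 / (1 + exp(-g * (x - M)))

where M is the mid-point (replication score at which half the cells have
replicated the bin; higher = later RT) and g the slope (gain).  T_width,
the replication-score span between 25% and 75% of cells replicated,
equals 2*ln(3)/g on the fitted curve and quantifies cell-to-cell RT
heterogeneity: larger T_width = less coordinated replication of that bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .grid import BinaryReplicationMatrix
from .rt import IntervalGrid, replication_score

TWO_LN3 = 2.0 * np.log(3.0)


@dataclass
class SigmoidFit:
    g: float
    m: float
    t_width: float
    converged: bool
    rss: float

    @classmethod
    def failed(cls) -> "SigmoidFit":
        return cls(np.nan, np.nan, np.nan, False, np.nan)


def _sigmoid(x: np.ndarray, g: float, m: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-np.clip(g * (x - m), -700, 700)))


def fit_sigmoid_bin(
    x: np.ndarray,
    y: np.ndarray,
    n_anchor: int = 16,
    g_bounds: tuple[float, float] = (1e-4, 1e3),
    m_bounds: tuple[float, float] = (-50.0, 150.0),
    max_iter: int = 200,
    n_restarts: int = 3,
    require_crossing: bool = True,
) -> SigmoidFit:
    """Nonlinear least-squares fit of the per-bin sigmoid.

    Starts are g = 0.1 and M = 100 - mean(y).  Before fitting, ``n_anchor``
    points at (0, 0) and ``n_anchor`` at (100, 100) are appended to anchor
    the start and end of the curve.  Failed fits (non-convergence, or —
    when ``require_crossing`` — observed y never crossing 50%) are
    returned with ``converged=False`` rather than extrapolated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        return SigmoidFit.failed()
    if np.any((y < 0) | (y > 100)):
        raise ValueError("y must be percentages in [0, 100]")
    if require_crossing and (y.max() < 50.0 or y.min() > 50.0):
        return SigmoidFit.failed()
    m0 = 100.0 - y.mean()
    xa = np.concatenate([x, np.zeros(n_anchor), np.full(n_anchor, 100.0)])
    ya = np.concatenate([y, np.zeros(n_anchor), np.full(n_anchor, 100.0)])

    def resid(theta):
        return _sigmoid(xa, theta[0], theta[1]) - ya

    lb = (g_bounds[0], m_bounds[0])
    ub = (g_bounds[1], m_bounds[1])
    starts = [(0.1, float(np.clip(m0, *m_bounds)))]
    rng = np.random.default_rng(0)
    for _ in range(n_restarts):  # jittered restarts, used only on failure
        starts.append((float(10 ** rng.uniform(-2, 0.5)),
                       float(rng.uniform(10, 90))))
    best = None
    for g0, mm0 in starts:
        try:
            res = least_squares(resid, (g0, mm0), bounds=(lb, ub),
                                method="trf", max_nfev=max_iter * 10,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
        if best is not None:
            break  # standard start succeeded; restarts are a failure fallback
    if best is None:
        return SigmoidFit.failed()
    rss, (g, m) = best
    if g <= 0:
        return SigmoidFit.failed()
    return SigmoidFit(float(g), float(m), t_width_from_g(float(g)), True, rss)


def t_width_from_g(g: float) -> float:
    """Replication-score span between 25% and 75% replicated: 2*ln(3)/g."""
    if not np.isfinite(g) or g <= 0:
        raise ValueError("t_width requires a converged fit with g > 0")
    return TWO_LN3 / g


def t_width_from_fit(fit: SigmoidFit) -> float:
    if not fit.converged:
        raise ValueError("t_width requires a converged fit")
    return t_width_from_g(fit.g)


def interval_xy(states: BinaryReplicationMatrix,
                grid: IntervalGrid | None = None,
                min_cells_per_interval: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval (x, Y): mean replication score and % replicated per bin.

    x[i] is the mean genome-wide replication score of the cells falling in
    score interval i; Y[i, j] the percentage of those cells that
    replicated bin j.  Intervals with fewer than ``min_cells_per_interval``
    cells give NaN rows.
    """
    grid = grid or IntervalGrid()
    scores = replication_score(states)
    member = grid.membership(scores)
    observed = states.unmasked()
    ones = (states.states == 1) & observed
    x = np.full(grid.n_intervals, np.nan)
    Y = np.full((grid.n_intervals, states.bins.n_bins), np.nan)
    for i in range(grid.n_intervals):
        cells = member[i]
        if cells.sum() < min_cells_per_interval:
            continue
        x[i] = scores[cells].mean()
        denom = observed[cells].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Y[i] = np.where(denom > 0,
                            100.0 * ones[cells].sum(axis=0) / denom, np.nan)
    return x, Y


def fit_genome(states: BinaryReplicationMatrix,
               grid: IntervalGrid | None = None,
               n_anchor: int = 16,
               n_restarts: int = 3) -> pd.DataFrame:
    """Fit the sigmoid for every bin; one row per bin (NaN where failed)."""
    x, Y = interval_xy(states, grid)
    rows = np.empty((states.bins.n_bins, 4))
    conv = np.zeros(states.bins.n_bins, dtype=bool)
    for j in range(states.bins.n_bins):
        fit = fit_sigmoid_bin(x, Y[:, j], n_anchor=n_anchor, n_restarts=n_restarts)
        rows[j] = (fit.g, fit.m, fit.t_width, fit.rss)
        conv[j] = fit.converged
    out = pd.DataFrame(rows, columns=["g", "M", "t_width", "rss"])
    out.insert(0, "bin", states.bins.keys())
    out["converged"] = conv
    return out


def t_width_m_contour(fits: pd.DataFrame, m_bins: int = 20,
                      t_bins: int = 20) -> pd.DataFrame:
    """Binned 2-D histogram of (M, T_width) over converged fits."""
    ok = fits["converged"] & np.isfinite(fits["t_width"])
    sub = fits.loc[ok]
    if sub.empty:
        raise ValueError("no converged fits")
    h, m_edges, t_edges = np.histogram2d(sub["M"], sub["t_width"],
                                         bins=(m_bins, t_bins))
    rows = []
    for i in range(m_bins):
        for j in range(t_bins):
            rows.append((0.5 * (m_edges[i] + m_edges[i + 1]),
                         0.5 * (t_edges[j] + t_edges[j + 1]), h[i, j]))
    return pd.DataFrame(rows, columns=["M_mid", "t_width_mid", "count"])
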