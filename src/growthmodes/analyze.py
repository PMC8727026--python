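"""Statistical constructs for per-cycle tables and length trajectories.

These are the exact procedures used on mother-machine data: ordinary
least squares on raw points, equal-width x-binning with a minimum-count
display filter, forward-difference growth-rate / elongation-speed
estimation, per-trajectory age binning (each trajectory contributes
equally to the final trend, which is what protects the growth-rate vs
age plot from inspection bias), time-from-event binning with the
mean-generation-time diagnostic, and the two-stage elongation-speed vs
size binning.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import CellCycleRecord, Trajectory
from .theory import RegressionResult

__all__ = [
    "BinnedTrend",
    "RateKind",
    "RateSeries",
    "EventKind",
    "ols_fit",
    "bin_xy",
    "rate_series",
    "growth_rate_vs_age",
    "growth_rate_vs_time_from_event",
    "elongation_speed_vs_size",
]


class RateKind(str, enum.Enum):
    GROWTH_RATE = "growth_rate"          # (1/L) dL/dt, 1/min
    ELONGATION_SPEED = "elongation_speed"  # dL/dt, um/min


class EventKind(str, enum.Enum):
    BIRTH = "birth"
    CONSTRICTION = "constriction"


@dataclass
class BinnedTrend:
    """Equal-width binned estimate of E[y | x].

    ``mean_y`` is NaN for masked bins (those with at most ``min_count``
    points — the display filter keeps bins with *more* than
    ``min_count``); ``n_per_bin`` always holds the raw counts.
    ``sem_y`` is the per-bin standard deviation scaled by 1/sqrt(n),
    i.e. a standard error.  ``aux_mean_Td`` is the mean generation time
    of the cells contributing to each bin, populated by the
    time-from-event analysis as its inspection-bias diagnostic.
    """

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_y: np.ndarray
    sd_y: np.ndarray
    sem_y: np.ndarray
    n_per_bin: np.ndarray
    min_count: int = 0
    aux_mean_Td: Optional[np.ndarray] = None

    @property
    def mask(self) -> np.ndarray:
        """True for bins that pass the minimum-count filter."""
        return self.n_per_bin > self.min_count


@dataclass
class RateSeries:
    """Forward-difference rates of one trajectory, indexed by age.

    Rates are attached to the left endpoint of each forward difference;
    extended trajectories yield ages above 1 computed from the summed
    daughter lengths.
    """

    ages: np.ndarray
    rates: np.ndarray
    times: np.ndarray
    kind: RateKind
    Td: float


# ----------------------------------------------------------------------
# regression and binning primitives
# ----------------------------------------------------------------------

def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares on raw points (never on binned data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
    )


def bin_xy(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int = 20,
    min_count: int = 15,
    edges: Optional[np.ndarray] = None,
    aux: Optional[Sequence[float]] = None,
) -> BinnedTrend:
    """Bin y by x into equal-width bins over the observed x-range.

    Bins are half-open ``[lo, hi)`` with the last bin closed.  Bins with
    at most ``min_count`` points are masked in ``mean_y`` but their raw
    counts are retained.  ``aux`` (e.g. per-point generation times) is
    averaged per bin into ``aux_mean_Td``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if edges is None:
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            hi = lo + 1.0  # single-valued x: one occupied bin
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        n_bins = edges.size - 1
    idx = np.digitize(x, edges[1:-1], right=False)  # [lo, hi), last closed
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    sqsums = np.bincount(idx, weights=y * y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = sqsums / counts - means**2
        sd = np.sqrt(np.clip(var, 0.0, None) * counts / np.maximum(counts - 1, 1))
        sem = sd / np.sqrt(counts)
    means = np.where(counts > min_count, means, np.nan)
    aux_mean = None
    if aux is not None:
        aux = np.asarray(aux, dtype=float)
        aux_sums = np.bincount(idx, weights=aux, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            aux_mean = np.where(counts > 0, aux_sums / np.maximum(counts, 1), np.nan)
    return BinnedTrend(
        bin_edges=edges,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_y=means,
        sd_y=np.where(counts > 1, sd, np.nan),
        sem_y=np.where(counts > 0, sem, np.nan),
        n_per_bin=counts,
        min_count=min_count,
        aux_mean_Td=aux_mean,
    )


# ----------------------------------------------------------------------
# trajectory-level rates
# ----------------------------------------------------------------------

def rate_series(traj: Trajectory, kind: RateKind | str = RateKind.GROWTH_RATE) -> RateSeries:
    """Forward-difference rate at each sample except the last.

    The growth rate at time t is ``(L(t+dt) - L(t)) / (dt * L(t))`` and
    the elongation speed drops the ``1/L(t)`` factor; the rate is
    indexed by the left endpoint, so its age is ``t / Td``.
    """
    kind = RateKind(kind)
    t = traj.times
    L = traj.lengths
    if t.size < 2:
        raise ValueError("trajectory needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    dL = np.diff(L)
    if kind is RateKind.GROWTH_RATE:
        rates = dL / (dt * L[:-1])
    else:
        rates = dL / dt
    return RateSeries(ages=t[:-1] / traj.Td, rates=rates, times=t[:-1], kind=kind, Td=traj.Td)


def growth_rate_vs_age(
    trajectories: Sequence[Trajectory],
    n_interp: int = 200,
    n_bins: int = 50,
    kind: RateKind | str = RateKind.GROWTH_RATE,
    max_age: Optional[float] = None,
) -> BinnedTrend:
    """Across-trajectory binned rate-vs-age trend with equal contributions.

    Per trajectory the forward-difference rate series is linearly
    interpolated onto ``n_interp`` equally spaced times, binned by age
    into ``n_bins`` bins, and averaged within each bin; the reported
    trend is the unweighted mean of those per-trajectory bin means over
    all trajectories (sd and sd/sqrt(N) across trajectories are the
    error bars).  Equal weighting of trajectories — rather than pooling
    samples — is what prevents slow-growing, long-lived cells from
    dominating late-age bins (inspection bias).

    ``max_age`` fixes the upper edge of the binning; by default it is
    1 for plain trajectories and the largest observed age when
    beyond-division extensions are present.
    """
    kind = RateKind(kind)
    if not trajectories:
        raise ValueError("no trajectories")
    series = [rate_series(tr, kind) for tr in trajectories]
    if max_age is None:
        top = max(float(s.ages[-1]) for s in series)
        max_age = max(1.0, top)
    edges = np.linspace(0.0, max_age, n_bins + 1)

    sums = np.zeros(n_bins)
    sqsums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for s in series:
        if s.ages.size < 2:
            raise ValueError("each trajectory must yield at least 2 rate points")
        t_grid = np.linspace(s.times[0], s.times[-1], n_interp)
        r_grid = np.interp(t_grid, s.times, s.rates)
        a_grid = t_grid / s.Td
        idx = np.digitize(a_grid, edges[1:-1], right=False)
        c = np.bincount(idx, minlength=n_bins)
        m = np.bincount(idx, weights=r_grid, minlength=n_bins)
        occupied = c > 0
        with np.errstate(invalid="ignore"):
            traj_means = m[occupied] / c[occupied]
        sums[occupied] += traj_means
        sqsums[occupied] += traj_means**2
        counts[occupied] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = sqsums / np.maximum(counts, 1) - means**2
        sd = np.sqrt(np.clip(var, 0.0, None) * counts / np.maximum(counts - 1, 1))
        sem = sd / np.sqrt(np.maximum(counts, 1))
    return BinnedTrend(
        bin_edges=edges,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_y=means,
        sd_y=np.where(counts > 1, sd, np.nan),
        sem_y=np.where(counts > 0, sem, np.nan),
        n_per_bin=counts,
        min_count=0,
    )


def growth_rate_vs_time_from_event(
    cycles: Sequence[CellCycleRecord],
    trajectories: Sequence[Trajectory],
    event: EventKind | str = EventKind.BIRTH,
    bin_width: float = 4.0,
    kind: RateKind | str = RateKind.GROWTH_RATE,
    min_count: int = 15,
) -> BinnedTrend:
    """Pooled rate binned by time relative to a cell-cycle event.

    Rates from all trajectories are pooled and binned by ``t - T_event``
    in bins of ``bin_width`` minutes.  ``aux_mean_Td`` carries the mean
    generation time of the cells contributing to each bin: a rise of
    that diagnostic marks bins dominated by long-lived cells, i.e.
    inspection bias, which is exactly where the pooled rate trend dips
    even for perfectly exponential cells.
    """
    event = EventKind(event)
    kind = RateKind(kind)
    by_gen = {c.generation: c for c in cycles}
    rel_t: list[np.ndarray] = []
    rates: list[np.ndarray] = []
    tds: list[np.ndarray] = []
    for tr in trajectories:
        rec = by_gen.get(tr.cycle_ref)
        if rec is None:
            continue
        if event is EventKind.BIRTH:
            t_event = 0.0
        else:
            if rec.Tn is None:
                continue
            t_event = rec.Tn
        s = rate_series(tr, kind)
        rel_t.append(s.times - t_event)
        rates.append(s.rates)
        tds.append(np.full_like(s.rates, rec.Td))
    if not rel_t:
        raise ValueError(f"no record carries the event {event.value!r}")
    x = np.concatenate(rel_t)
    y = np.concatenate(rates)
    td = np.concatenate(tds)
    lo = math.floor(float(x.min()) / bin_width) * bin_width
    hi = math.ceil(float(x.max()) / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 2)
    edges = np.linspace(lo, lo + n_bins * bin_width, n_bins + 1)
    return bin_xy(x, y, min_count=min_count, edges=edges, aux=td)


def elongation_speed_vs_size(
    trajectories: Sequence[Trajectory],
    n_bins_per_traj: int = 10,
    n_bins_pooled: int = 20,
    min_count: int = 15,
) -> tuple[BinnedTrend, RegressionResult]:
    """Two-stage elongation-speed vs size binning, plus OLS readout.

    Each trajectory is binned into ``n_bins_per_traj`` equal-width size
    bins and its per-bin mean speed and size are pooled over all
    trajectories; the final trend bins the pooled averages by size, and
    the returned regression is OLS on the pooled averages (slope ~ mean
    growth rate for exponential growth; intercept ~ mean speed for
    linear growth).
    """
    if not trajectories:
        raise ValueError("empty trajectory pool")
    pooled_sizes: list[float] = []
    pooled_speeds: list[float] = []
    for tr in trajectories:
        s = rate_series(tr, RateKind.ELONGATION_SPEED)
        sizes = tr.lengths[:-1]
        lo, hi = float(sizes.min()), float(sizes.max())
        if lo == hi:
            pooled_sizes.append(lo)
            pooled_speeds.append(float(s.rates.mean()))
            continue
        edges = np.linspace(lo, hi, n_bins_per_traj + 1)
        idx = np.digitize(sizes, edges[1:-1], right=False)
        c = np.bincount(idx, minlength=n_bins_per_traj)
        sum_v = np.bincount(idx, weights=s.rates, minlength=n_bins_per_traj)
        sum_s = np.bincount(idx, weights=sizes, minlength=n_bins_per_traj)
        occ = c > 0
        pooled_speeds.extend((sum_v[occ] / c[occ]).tolist())
        pooled_sizes.extend((sum_s[occ] / c[occ]).tolist())
    trend = bin_xy(pooled_sizes, pooled_speeds, n_bins=n_bins_pooled, min_count=min_count)
    fit = ols_fit(pooled_sizes, pooled_speeds)
    return trend, fit
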