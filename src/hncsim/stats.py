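"""Statistics on simulated or empirical clone time series.

Burst detection on the event clock, empirical clone-size distributions
and the mean-rescaling ("scaling law") transform, the Shannon diversity
index of clone fractions, and simulation-based inversion of diversity
or burst-duration observations into an estimate of the master-cell
supply rate epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq, isotonic_regression

from . import _kernels
from .bursts import mean_burst_duration
from .exceptions import (
    DataError,
    DomainError,
    EstimationError,
    ExtrapolationError,
)
from .model import ModelParams
from .simulate import LabeledCloneEnsemble, uniform_state
from .stationary import CloneSizeDistribution, stationary_distribution

__all__ = [
    "Burst",
    "ScaledDistribution",
    "DiversityEstimate",
    "EpsilonEstimate",
    "detect_bursts",
    "detect_excursions",
    "clone_size_distribution",
    "scale_distribution",
    "scaling_collapse_statistic",
    "shannon_index",
    "expected_shannon_index",
    "shannon_curve",
    "estimate_epsilon_from_shannon",
    "estimate_epsilon_from_burst_duration",
    "invert_expected_shannon",
]


# ---------------------------------------------------------------------------
# bursts on the event clock
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Burst:
    """One excursion of a clone from size 0 up to ``height`` and back.

    ``start_step`` is the step of the last entry into size 0 before the
    excursion (or the series start), so the duration includes the
    waiting time at zero — the same convention as the analytic expected
    duration, whose leading term is that waiting time's expectation.
    """

    clone: int
    start_step: int
    end_step: int
    height: int
    depart_step: int = -1
    censored: bool = False

    def __post_init__(self) -> None:
        if self.depart_step < 0:
            object.__setattr__(self, "depart_step", self.start_step + 1)

    @property
    def duration(self) -> int:
        """Steps from the last entry into size 0 through the return to 0."""
        return self.end_step - self.start_step

    @property
    def excursion_duration(self) -> int:
        """Steps the clone is actually present (appearance to return).

        Excludes the waiting time at size 0, matching what a
        lineage-tracing experiment can observe and the default
        convention of :func:`hncsim.bursts.mean_burst_duration`.
        """
        return self.end_step - self.depart_step


def _validate_series(series: np.ndarray, event_clock: bool) -> np.ndarray:
    arr = np.asarray(series)
    if arr.ndim != 1:
        raise DataError("series must be one-dimensional")
    if np.any(arr < 0):
        raise DataError("clone sizes must be non-negative")
    if event_clock and arr.size > 1 and np.any(np.abs(np.diff(arr)) > 1):
        raise DataError(
            "series is not on the event clock (consecutive values differ "
            "by more than 1); use detect_excursions for coarsely sampled data"
        )
    return arr.astype(np.int64)


def detect_bursts(
    series: Sequence[int], clone: int = 0, include_censored: bool = False
) -> list[Burst]:
    """Partition an event-clock size series into bursts.

    Each maximal segment strictly between two visits to size 0 yields
    one completed burst; its height is the segment maximum, its start
    the last *entry* into 0 before the segment (so repeated steps at 0
    count toward the duration).  An excursion still open at the series
    end is returned only when ``include_censored`` is set, flagged as
    censored.
    """
    arr = _validate_series(series, event_clock=True)
    zeros = np.flatnonzero(arr == 0)
    bursts: list[Burst] = []

    if zeros.size == 0:
        if include_censored:
            bursts.append(
                Burst(clone=clone, start_step=0, end_step=arr.size - 1,
                      height=int(arr.max()), depart_step=0, censored=True)
            )
        return bursts

    # First index of the zero-run each zero belongs to ("entry into 0").
    new_run = np.empty(zeros.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = zeros[1:] != zeros[:-1] + 1
    run_first = zeros[new_run][np.cumsum(new_run) - 1]

    if arr[0] > 0:  # excursion open at the series start
        bursts.append(
            Burst(clone=clone, start_step=0, end_step=int(zeros[0]),
                  height=int(arr[: zeros[0]].max()), depart_step=0)
        )

    # A completed burst sits between consecutive zeros with a gap.
    gap = np.flatnonzero(zeros[1:] > zeros[:-1] + 1)  # index of zero before seg
    if gap.size:
        seg_lo = zeros[gap] + 1
        seg_hi = zeros[gap + 1]  # exclusive
        bounds = np.empty(2 * gap.size, dtype=np.int64)
        bounds[0::2] = seg_lo
        bounds[1::2] = seg_hi
        heights = np.maximum.reduceat(arr, bounds)[0::2]
        starts = run_first[gap]
        for s, lo, hi, hgt in zip(starts, seg_lo, seg_hi, heights):
            bursts.append(
                Burst(clone=clone, start_step=int(s), end_step=int(hi),
                      height=int(hgt), depart_step=int(lo))
            )

    if zeros[-1] < arr.size - 1 and include_censored:
        bursts.append(
            Burst(clone=clone, start_step=int(run_first[-1]),
                  end_step=arr.size - 1,
                  height=int(arr[zeros[-1] + 1 :].max()),
                  depart_step=int(zeros[-1] + 1), censored=True)
        )
    return bursts


def detect_excursions(
    series: Sequence[float], floor: float = 0.0, clone: int = 0
) -> list[Burst]:
    """Descriptive burst-like excursions for coarsely sampled tables.

    Relaxation of :func:`detect_bursts` for empirical data sampled at
    intervals (e.g. months) where the event-clock precondition fails:
    maximal runs of values strictly above ``floor`` are reported, with
    the height of the run maximum.  Durations are in sampling units and
    are not comparable to the analytic step-clock durations.
    """
    arr = np.asarray(series, dtype=float)
    if np.any(arr < 0):
        raise DataError("clone sizes must be non-negative")
    above = arr > floor
    bursts: list[Burst] = []
    i = 0
    while i < arr.size:
        if above[i]:
            j = i
            while j < arr.size and above[j]:
                j += 1
            bursts.append(
                Burst(
                    clone=clone,
                    start_step=max(i - 1, 0),
                    end_step=min(j, arr.size - 1),
                    height=int(np.ceil(arr[i:j].max())),
                    censored=j == arr.size,
                )
            )
            i = j
        else:
            i += 1
    return bursts


# ---------------------------------------------------------------------------
# distributions and the scaling transform
# ---------------------------------------------------------------------------

def clone_size_distribution(
    ensemble: LabeledCloneEnsemble,
    timepoint: int,
    condition_on_survival: bool = False,
) -> CloneSizeDistribution:
    """Empirical labeled-clone size pmf across replicates at a recorded step.

    With ``condition_on_survival`` the pmf is restricted to sizes >= 1
    and renormalized — the convention under which scaling-law collapses
    are reported, since the unconditioned law accumulates mass at 0.
    """
    sizes = ensemble.sizes_at(timepoint)
    N = ensemble.params.N
    counts = np.bincount(sizes, minlength=N + 1).astype(float)
    if condition_on_survival:
        counts[0] = 0.0
        if counts.sum() == 0:
            raise EstimationError(
                f"no surviving labeled clones at step {timepoint}"
            )
    pmf = counts / counts.sum()
    return CloneSizeDistribution(pmf=pmf, label=int(timepoint))


@dataclass
class ScaledDistribution:
    """A clone-size pmf rescaled by its mean: x = n/<n>, density <n>*P_n.

    ``weights`` keeps the underlying probability masses so that exact
    Kolmogorov-Smirnov comparisons between scaled distributions remain
    possible after the transform.
    """

    x: np.ndarray
    density: np.ndarray
    weights: np.ndarray
    mean_clone_size: float
    label: Union[int, str]


def scale_distribution(dist: CloneSizeDistribution) -> ScaledDistribution:
    """Mean-rescale a clone-size distribution.

    The transform is mean-preserving: the first moment of the scaled
    distribution is exactly 1.
    """
    mean = dist.mean()
    if mean <= 0:
        raise DomainError("cannot scale a distribution with zero mean")
    return ScaledDistribution(
        x=dist.support / mean,
        density=mean * dist.pmf,
        weights=dist.pmf.copy(),
        mean_clone_size=mean,
        label=dist.label,
    )


def _cell_cdf(dist: ScaledDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-ogive CDF nodes of a scaled lattice distribution.

    Each atom's mass is spread uniformly over its lattice cell (the
    interval between the midpoints to its neighbours), giving a
    piecewise-linear CDF whose nodes are the cell edges.  Clipped at 0
    on the left since clone sizes are non-negative.
    """
    keep = dist.weights > 0
    x = dist.x[keep]
    w = dist.weights[keep]
    w = w / w.sum()
    if x.size == 1:
        half = x[0] / 2 if x[0] > 0 else 0.5
        edges = np.array([x[0] - half, x[0] + half])
    else:
        mid = (x[:-1] + x[1:]) / 2.0
        edges = np.concatenate(
            ([max(x[0] - (x[1] - x[0]) / 2.0, 0.0)], mid, [x[-1] + (x[-1] - x[-2]) / 2.0])
        )
    return edges, np.concatenate(([0.0], np.cumsum(w)))


def _ks_distance(a: ScaledDistribution, b: ScaledDistribution) -> float:
    """KS distance between two scaled distributions (histogram-CDF form).

    A mean-rescaled lattice pmf is a discrete estimate of a continuous
    scaling function on a grid of spacing 1/mean; distributions at
    different times live on different grids, so the raw step-CDF
    sup-distance is dominated by grid misalignment (an O(1/mean) atom
    offset) rather than by shape.  Each distribution is therefore
    converted to the piecewise-linear CDF of its cell-smeared histogram
    and the sup-distance is taken between the two interpolants over the
    union of their nodes.  Identical inputs give exactly 0.
    """
    xa, fa = _cell_cdf(a)
    xb, fb = _cell_cdf(b)
    grid = np.union1d(xa, xb)
    ga = np.interp(grid, xa, fa, left=0.0, right=1.0)
    gb = np.interp(grid, xb, fb, left=0.0, right=1.0)
    return float(np.max(np.abs(ga - gb)))


def scaling_collapse_statistic(dists: Sequence[ScaledDistribution]) -> float:
    """Maximum pairwise KS distance between scaled distributions.

    Small values mean the mean-rescaled distributions coincide — the
    scaling law holds (neutral competition); large values mean the
    shape itself changes over time, as in the purely hierarchical model
    where the distribution relaxes toward a binomial of fixed mean.
    """
    if len(dists) < 2:
        raise DomainError("need at least two scaled distributions to compare")
    score = 0.0
    for i in range(len(dists)):
        for j in range(i + 1, len(dists)):
            score = max(score, _ks_distance(dists[i], dists[j]))
    return score


# ---------------------------------------------------------------------------
# diversity and epsilon estimation
# ---------------------------------------------------------------------------

@dataclass
class DiversityEstimate:
    """Shannon index of a set of clone fractions, in nats."""

    shannon_h: float
    n_clones: int
    fractions: np.ndarray


def shannon_index(fractions: Sequence[float]) -> float:
    """Shannon diversity H = -sum_m P_m ln P_m (nats).

    Zero fractions contribute zero by the 0*ln(0) = 0 convention; the
    index is bounded by ln(M) for M clones.
    """
    p = np.asarray(fractions, dtype=float)
    if np.any(p < 0):
        raise DataError("clone fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise DataError(f"clone fractions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def expected_shannon_index(params: ModelParams) -> float:
    """Exact expected Shannon index of clone fractions at stationarity.

    Clones are exchangeable, so E[-sum_k p_k ln p_k] = -K E[p ln p]
    with p = n/N distributed by the closed-form stationary marginal.
    Used as the analytic cross-check for the simulated diversity curve.
    """
    dist = stationary_distribution(params)
    n = dist.support
    p = n / params.N
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n > 0, -p * np.log(np.where(n > 0, p, 1.0)), 0.0)
    return float(params.K * (f @ dist.pmf))


def invert_expected_shannon(
    H_obs: float,
    N: int,
    K: int,
    lam: float = 1.0,
    bracket: tuple[float, float] = (1e-4, 5.0),
) -> float:
    """Invert the exact stationary Shannon map H(eps) at an observed index.

    Uses the closed-form expected index (see
    :func:`expected_shannon_index`), which is strictly increasing in
    epsilon, so no simulation is needed.  Useful at large K where a
    simulated grid would be slow; the simulation-based estimator
    additionally yields an uncertainty band.
    """
    lo, hi = bracket

    def f(eps: float) -> float:
        return expected_shannon_index(ModelParams(K=K, N=N, epsilon=eps, lam=lam)) - H_obs

    if f(lo) > 0 or f(hi) < 0:
        raise ExtrapolationError(
            f"H_obs = {H_obs} outside the map range on epsilon in [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


@dataclass
class EpsilonEstimate:
    """Point estimate of epsilon with a Monte-Carlo uncertainty band."""

    value: float
    low: float
    high: float
    grid: np.ndarray = field(repr=False)
    curve: np.ndarray = field(repr=False)
    curve_se: np.ndarray = field(repr=False)


def shannon_curve(
    N: int,
    K: int,
    eps_grid: Sequence[float],
    lam: float = 1.0,
    n_snapshots: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated mean Shannon index (and its SE) across an epsilon grid.

    Per grid point the multi-clone process is burned in for 100
    calibrated time units (100 * (lam*N + eps*K) steps), then the index
    is averaged over ``n_snapshots`` snapshots.  Clone composition
    renews on the burst/turnover timescale, which grows like
    (lam*N + eps*K)/eps for small supply, so snapshots are thinned by
    twice that interval; the SE comes from ten batch means, the
    standard guard against residual autocorrelation.
    """
    eps_grid = np.asarray(eps_grid, dtype=float)
    means = np.empty(eps_grid.size)
    ses = np.empty(eps_grid.size)
    for i, eps in enumerate(eps_grid):
        params = ModelParams(K=K, N=N, epsilon=float(eps), lam=lam)
        counts0 = uniform_state(params)
        burn = int(round(100 * params.total_rate))
        thin = int(round(2 * params.total_rate / eps))
        snaps = _kernels.shannon_snapshots(
            counts0, params.epsilon, params.lam, burn, n_snapshots, thin,
            seed + i,
        )
        means[i] = snaps.mean()
        n_batches = min(10, n_snapshots)
        batches = np.array_split(snaps, n_batches)
        bm = np.array([b.mean() for b in batches])
        ses[i] = bm.std(ddof=1) / np.sqrt(n_batches)
    return means, ses


def estimate_epsilon_from_shannon(
    H_obs: float,
    N: int,
    K: int,
    eps_grid: Sequence[float],
    lam: float = 1.0,
    sim_budget: int = 200,
    seed: int = 0,
) -> EpsilonEstimate:
    """Invert an observed Shannon index into an epsilon estimate.

    Simulates the model to stationarity across ``eps_grid``, fits a
    monotone (isotonic, then piecewise-linear) interpolant of the mean
    Shannon index — more master-cell supply always evens out the clones,
    so H(eps) is increasing — and inverts it at ``H_obs``.  The band is
    obtained by inverting H_obs +/- 1.96 SE of the local curve.
    """
    eps_grid = np.sort(np.asarray(eps_grid, dtype=float))
    if eps_grid.size < 2:
        raise DomainError("eps_grid needs at least two points")
    if H_obs < 0 or H_obs > np.log(K) + 1e-9:
        raise DomainError(f"H_obs must lie in [0, ln K = {np.log(K):.4f}]")
    means, ses = shannon_curve(
        N, K, eps_grid, lam=lam, n_snapshots=sim_budget, seed=seed
    )
    iso = isotonic_regression(means).x

    def invert(h: float) -> float:
        return float(np.interp(h, iso, eps_grid))

    lo_h, hi_h = iso[0], iso[-1]
    if H_obs > hi_h:
        if H_obs <= np.log(K) + 1e-9:
            warnings.warn(
                "observed Shannon index exceeds the simulated range: clone "
                "fractions are hierarchical-model-even; returning the top of "
                "the epsilon grid (saturation)",
                stacklevel=2,
            )
            top = float(eps_grid[-1])
            return EpsilonEstimate(top, top, top, eps_grid, means, ses)
        raise ExtrapolationError(f"H_obs = {H_obs} above simulated range")
    if H_obs < lo_h:
        raise ExtrapolationError(
            f"H_obs = {H_obs} below simulated range [{lo_h:.4f}, {hi_h:.4f}]"
        )
    se_local = float(np.interp(invert(H_obs), eps_grid, ses))
    return EpsilonEstimate(
        value=invert(H_obs),
        low=invert(max(H_obs - 1.96 * se_local, lo_h)),
        high=invert(min(H_obs + 1.96 * se_local, hi_h)),
        grid=eps_grid,
        curve=means,
        curve_se=ses,
    )


def estimate_epsilon_from_burst_duration(
    mean_dur_obs: float,
    N: int,
    K: int,
    eps_grid: Sequence[float] = (1e-3, 2.0),
    lam: float = 1.0,
    H_max: Optional[int] = None,
    sampling_interval: int = 1,
) -> float:
    """Invert an observed mean burst duration (steps) into epsilon.

    Uses the analytic census-weighted mean excursion duration and
    solves for the root with Brent's method over the bracket spanned by
    ``eps_grid``.  The map is monotone increasing in epsilon in the
    small-K burst regime (e.g. K = 10, N = 100), but at large K strong
    total supply shortens above-average excursions and the map can turn
    over; monotonicity is therefore verified on a coarse grid inside
    the bracket first, and a non-invertible bracket is refused.

    Burst durations are defined on the event clock; data sampled at
    coarser intervals cannot resolve them, so ``sampling_interval > 1``
    is refused rather than silently producing a biased estimate.
    """
    if sampling_interval > 1:
        raise DataError(
            "mean burst duration requires event-resolution series "
            f"(sampling_interval = 1), got {sampling_interval}; coarse "
            "tables cannot resolve burst durations"
        )
    if mean_dur_obs <= 0:
        raise DomainError("mean_dur_obs must be positive")
    if H_max is None:
        H_max = N - 1
    lo, hi = float(np.min(eps_grid)), float(np.max(eps_grid))

    def f(eps: float) -> float:
        params = ModelParams(K=K, N=N, epsilon=eps, lam=lam)
        return mean_burst_duration(params, H_max) - mean_dur_obs

    probe = np.geomspace(lo, hi, 7)
    vals = np.array([f(e) for e in probe])
    if np.any(np.diff(vals) < 0):
        raise EstimationError(
            "mean burst duration is not monotone in epsilon over "
            f"[{lo}, {hi}] at K={K}, N={N}; narrow the bracket to a "
            "monotone branch before inverting"
        )
    if vals[0] * vals[-1] > 0:
        raise ExtrapolationError(
            f"observed mean duration {mean_dur_obs} outside the range of the "
            f"analytic map on epsilon in [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
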