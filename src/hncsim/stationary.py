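"""Exact single-clone distribution dynamics.

The size of one clone is a birth-death chain on {0, ..., N} with
one-step probabilities r_up(n), r_down(n).  Its distribution evolves
under the tridiagonal master equation

    P_n(m+1) = r_up(n-1) P_{n-1}(m) + r_down(n+1) P_{n+1}(m)
               + (1 - r_up(n) - r_down(n)) P_n(m),

and, for epsilon > 0, detailed balance r_down(n) P_n = r_up(n-1) P_{n-1}
yields the closed-form stationary law

    P_n(inf)  proportional to  prod_{k=1..n} r_up(k-1) / r_down(k).

The unnormalized products span hundreds of orders of magnitude for
N ~ 1000, so they are accumulated in log space and normalized with a
log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import logsumexp

from .exceptions import DistributionError, DomainError, ParameterError
from .model import ModelParams, transition_rate_tables

__all__ = [
    "CloneSizeDistribution",
    "evolve_master_equation",
    "stationary_distribution",
    "total_variation",
]

_NORM_TOL = 1e-10


@dataclass
class CloneSizeDistribution:
    """Probability mass over clone sizes n = 0..N.

    ``label`` is the step index the distribution refers to, or the
    string ``"stationary"``.
    """

    pmf: np.ndarray
    label: Union[int, str]

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 1 or self.pmf.size < 1:
            raise DistributionError("pmf must be a 1-D vector over n = 0..N")
        if np.any(self.pmf < -_NORM_TOL):
            raise DistributionError("pmf entries must be non-negative")
        if abs(self.pmf.sum() - 1.0) > _NORM_TOL:
            raise DistributionError(
                f"pmf must sum to 1 within {_NORM_TOL}, got {self.pmf.sum()!r}"
            )

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.pmf.size)

    def mean(self) -> float:
        return float(self.support @ self.pmf)

    def tail_mass(self, threshold: float) -> float:
        """Total mass at sizes strictly greater than ``threshold``."""
        return float(self.pmf[self.support > threshold].sum())


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on the same support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p - q).sum())


def evolve_master_equation(
    params: ModelParams, p0: CloneSizeDistribution, m: int
) -> CloneSizeDistribution:
    """Apply the tridiagonal master-equation update exactly ``m`` times.

    The update is a stochastic matrix, so probability mass is conserved
    at every iterate; a final renormalization only mops up float round-off.
    Repeated dense application is O(m*N) and exact, which is trivially
    fast for the lattice sizes this model uses.
    """
    if m < 0:
        raise DomainError("m must be >= 0")
    if p0.pmf.size != params.N + 1:
        raise DistributionError(
            f"p0 must have length N+1 = {params.N + 1}, got {p0.pmf.size}"
        )
    r_up, r_down = transition_rate_tables(params)
    stay = 1.0 - r_up - r_down
    p = p0.pmf.copy()
    for _ in range(m):
        nxt = stay * p
        nxt[1:] += r_up[:-1] * p[:-1]
        nxt[:-1] += r_down[1:] * p[1:]
        p = nxt
    p /= p.sum()
    label = p0.label + m if isinstance(p0.label, (int, np.integer)) else p0.label
    return CloneSizeDistribution(pmf=p, label=label)


def stationary_distribution(params: ModelParams) -> CloneSizeDistribution:
    """Closed-form stationary clone-size distribution (requires epsilon > 0).

    For epsilon = 0 the state n = 0 is absorbing and the detailed-balance
    product formally collapses onto it, misrepresenting the true
    absorbing mixture between extinction and fixation; that case is
    rejected rather than silently returning a point mass.
    """
    if params.epsilon == 0:
        raise ParameterError(
            "stationary_distribution requires epsilon > 0: with epsilon = 0 "
            "the boundary n = 0 is absorbing and no stationary law on "
            "{0..N} exists (the chain ends in the extinction/fixation mixture)"
        )
    N = params.N
    if params.K == 1:
        # Single clone: every compensation refills the same label, n = N
        # is reached and never left.
        pmf = np.zeros(N + 1)
        pmf[N] = 1.0
        return CloneSizeDistribution(pmf=pmf, label="stationary")
    r_up, r_down = transition_rate_tables(params)
    with np.errstate(divide="ignore"):
        log_ratio = np.log(r_up[:-1]) - np.log(r_down[1:])
    log_w = np.concatenate(([0.0], np.cumsum(log_ratio)))
    pmf = np.exp(log_w - logsumexp(log_w))
    pmf /= pmf.sum()
    return CloneSizeDistribution(pmf=pmf, label="stationary")
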