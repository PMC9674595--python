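"""First-passage theory of clonal bursts.

A burst of height H is an excursion of a clone's size from 0 up to H
and back to 0 without ever reaching H + 1.  Splitting into the forward
leg (1 -> H before 0) and backward leg (H -> 0 before H + 1) of the
embedded birth-death chain gives

    P_gen(H) = r_up(0) * P_fwd(1; H) * P_bwd(H; H+1),

the probability per step spent at size 0 that a burst of exactly
height H is initiated, with the classic gambler's-ruin closed forms

    P_fwd(1; H)   = (1 + sum_{j=1..H-1} prod_{k=1..j} rho_k)^-1,
    P_bwd(H; H+1) = (1 + sum_{j=1..H}   prod_{k=j..H} 1/rho_k)^-1,

where rho_k = r_down(k) / r_up(k).  Expected durations cannot be read
off a naive first-passage recurrence (the absorbing boundary at 0 makes
it ill-posed), so each leg uses the product transform
X(n) = P_split(n) * T_cond(n), which satisfies a well-posed tridiagonal
system with zero boundaries:

    (r_up(n) + r_down(n)) X(n) - r_up(n) X(n+1) - r_down(n) X(n-1) = P_split(n).

The expected burst duration on the step clock is then

    T_gen(H) = 1/r_up(0) + X_fwd(1)/P_fwd(1; H) + X_bwd(H)/P_bwd(H; H+1),

whose first term is the geometric waiting time at size 0; the matching
empirical convention (a burst starts at the last entry into size 0) is
applied by the burst detector, so analytic and census durations are
directly comparable.

Products of the ratios rho_k span many orders of magnitude for small
epsilon, so all sums of products accumulate in log space, and the
linear systems are solved by direct banded elimination rather than by
propagating the recurrences one-way.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import logsumexp

from .exceptions import DomainError, ParameterError
from .model import ModelParams, steps_to_time, transition_rate_tables

__all__ = [
    "splitting_forward",
    "splitting_backward",
    "burst_probability",
    "burst_expected_duration",
    "mean_burst_duration",
    "burst_table",
]


def _log_rho(params: ModelParams, upto: int) -> np.ndarray:
    """log(r_down(k)/r_up(k)) for k = 1..upto; validates positivity."""
    r_up, r_down = transition_rate_tables(params)
    ru = r_up[1 : upto + 1]
    rd = r_down[1 : upto + 1]
    if np.any(ru <= 0):
        k = 1 + int(np.argmax(ru <= 0))
        raise DomainError(f"r_up({k}) = 0: forward passage through {k} is blocked")
    if np.any(rd <= 0):
        k = 1 + int(np.argmax(rd <= 0))
        raise DomainError(f"r_down({k}) = 0: backward passage through {k} is blocked")
    return np.log(rd) - np.log(ru)


def splitting_forward(params: ModelParams, H: int) -> float:
    """P_fwd(1; H): probability of reaching H from size 1 before size 0."""
    if not 1 <= H <= params.N:
        raise DomainError(f"H must lie in [1, {params.N}], got {H}")
    if H == 1:
        return 1.0
    csum = np.cumsum(_log_rho(params, H - 1))  # log prod_{k=1..j} rho_k
    return float(np.exp(-np.logaddexp(0.0, logsumexp(csum))))


def splitting_backward(params: ModelParams, H: int) -> float:
    """P_bwd(H; H+1): probability of reaching 0 from H before H + 1."""
    if not 1 <= H <= params.N - 1:
        raise DomainError(f"H must lie in [1, {params.N - 1}], got {H}")
    log_inv = -_log_rho(params, H)  # log(r_up/r_down), k = 1..H
    suffix = np.cumsum(log_inv[::-1])  # j = H..1: log prod_{k=j..H}
    return float(np.exp(-np.logaddexp(0.0, logsumexp(suffix))))


def burst_probability(params: ModelParams, H: int) -> float:
    """P_gen(H): per-step-at-zero probability of a burst of exact height H."""
    if not 1 <= H <= params.N - 1:
        raise DomainError(f"H must lie in [1, {params.N - 1}], got {H}")
    if params.epsilon == 0:
        warnings.warn(
            "epsilon = 0: r_up(0) = 0, so no bursts start from size 0 "
            "in the NC model; returning 0",
            stacklevel=2,
        )
        return 0.0
    r_up0 = (params.epsilon / params.total_rate)
    return r_up0 * splitting_forward(params, H) * splitting_backward(params, H)


def _splitting_profile(params: ModelParams, H: int, forward: bool) -> np.ndarray:
    """Full splitting-probability profile on the {0..H} lattice, log-stable.

    forward=True : p[n] = P(hit H before 0 | start n), n = 0..H.
    forward=False: p[n] = P(hit 0 before H | start n) = 1 - the above.
    Uses partial sums of S_j = prod_{k=1..j} rho_k with S_0 = 1.
    """
    log_S = np.concatenate(([0.0], np.cumsum(_log_rho(params, H - 1))))  # j=0..H-1
    log_cum = np.logaddexp.accumulate(log_S)  # log sum_{j<=n} S_j
    p = np.empty(H + 1)
    p[0] = 0.0
    p[1:] = np.exp(log_cum - log_cum[-1])
    p[H] = 1.0
    return p if forward else 1.0 - p


def _xt_solve(params: ModelParams, H_wall: int, p_split: np.ndarray) -> np.ndarray:
    """Solve the tridiagonal X-system on interior states 1..H_wall-1.

    (r_up(n)+r_down(n)) X(n) - r_up(n) X(n+1) - r_down(n) X(n-1) = p_split[n],
    with X(0) = X(H_wall) = 0.  Returns the full vector X over 0..H_wall.
    """
    r_up, r_down = transition_rate_tables(params)
    idx = np.arange(1, H_wall)
    if idx.size == 0:
        return np.zeros(H_wall + 1)
    ru = r_up[idx]
    rd = r_down[idx]
    if np.any(ru + rd <= 0):
        n_bad = int(idx[np.argmax(ru + rd <= 0)])
        raise DomainError(f"state {n_bad} is blocking (r_up + r_down = 0)")
    ab = np.zeros((3, idx.size))
    ab[0, 1:] = -ru[:-1]  # superdiagonal: -r_up(n) X(n+1)
    ab[1] = ru + rd
    ab[2, :-1] = -rd[1:]  # subdiagonal: -r_down(n) X(n-1)
    x_int = solve_banded((1, 1), ab, p_split[idx])
    x = np.zeros(H_wall + 1)
    x[idx] = x_int
    return x


def burst_expected_duration(params: ModelParams, H: int) -> float:
    """T_gen(H): expected duration, in steps, of a burst of height H.

    Includes the geometric waiting time at size 0 (expectation
    1/r_up(0)) plus the conditional forward and backward passage times.
    Convert with :func:`hncsim.model.steps_to_time` if calibrated time
    is wanted.
    """
    if not 1 <= H <= params.N - 1:
        raise DomainError(f"H must lie in [1, {params.N - 1}], got {H}")
    if params.epsilon == 0:
        raise ParameterError("burst durations require epsilon > 0 (r_up(0) > 0)")
    r_up0 = params.epsilon / params.total_rate

    # Forward leg on {0..H}: T_fwd(1;H) = X(1)/P_fwd(1;H); zero when H == 1.
    if H == 1:
        t_fwd = 0.0
    else:
        p_fwd = _splitting_profile(params, H, forward=True)
        if p_fwd[1] == 0.0:
            raise DomainError(
                f"P_fwd(1;{H}) underflows to zero: bursts of this height are "
                "too rare to carry a finite-precision conditional duration"
            )
        x_fwd = _xt_solve(params, H, p_fwd)
        t_fwd = x_fwd[1] / p_fwd[1]

    # Backward leg on {0..H+1}: T_bwd(H;H+1) = X(H)/P_bwd(H;H+1).
    p_bwd = _splitting_profile(params, H + 1, forward=False)
    x_bwd = _xt_solve(params, H + 1, p_bwd)
    t_bwd = x_bwd[H] / p_bwd[H]

    return 1.0 / r_up0 + t_fwd + t_bwd


def mean_burst_duration(
    params: ModelParams, H_max: int, include_waiting: bool = False
) -> float:
    """P_gen-weighted mean duration over burst heights 1..H_max (steps).

    This is the expected duration of a burst drawn at random from a
    long trajectory's census.  By default the *excursion* convention is
    used — the time from the clone's appearance (first up-step out of
    0) to its return to 0, i.e. T_gen(H) - 1/r_up(0) — because that is
    the interval a lineage-tracing experiment can observe: while the
    clone sits at size 0 it is simply absent.  The excursion mean is
    monotone increasing in epsilon at fixed N, which is what makes it
    usable for estimation.  ``include_waiting`` switches to the full
    convention whose leading term, the expected wait (lam*N +
    epsilon*K)/epsilon at size 0, diverges for small epsilon and
    destroys that monotonicity.
    """
    if params.epsilon == 0:
        raise DomainError("all P_gen vanish when epsilon = 0")
    if not 1 <= H_max <= params.N - 1:
        raise DomainError(f"H_max must lie in [1, {params.N - 1}], got {H_max}")
    p = np.array([burst_probability(params, H) for H in range(1, H_max + 1)])
    # Heights whose generation probability underflows contribute nothing
    # to the weighted mean; skip them rather than evaluating 0 * inf.
    t = np.array(
        [
            burst_expected_duration(params, H) if p[H - 1] > 0 else 0.0
            for H in range(1, H_max + 1)
        ]
    )
    if not include_waiting:
        t = np.where(p > 0, t - params.total_rate / params.epsilon, 0.0)
    total = p.sum()
    if total <= 0:
        raise DomainError("all burst probabilities are zero")
    return float((p * t).sum() / total)


def burst_table(params: ModelParams, H_max: int) -> pd.DataFrame:
    """Tabulate P_gen and T_gen for H = 1..H_max (steps and calibrated time)."""
    rows = []
    for H in range(1, H_max + 1):
        t_steps = burst_expected_duration(params, H)
        rows.append(
            {
                "H": H,
                "p_gen": burst_probability(params, H),
                "t_gen_steps": t_steps,
                "t_gen_time": steps_to_time(params, t_steps),
            }
        )
    return pd.DataFrame(rows)
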