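"""Independent oracles used by the tests.

These deliberately avoid the closed forms and the P x T transform used
by the package: splitting probabilities and conditional passage times
come from dense fundamental-matrix linear algebra on the absorbing
chain, and stationary laws from the dominant eigenvector of the dense
transition matrix.  Agreement between these routes and the package is
the core correctness evidence for the first-passage analytics.
"""

from __future__ import annotations

import numpy as np

from hncsim import ModelParams, transition_rate_tables


def dense_transition_matrix(params: ModelParams) -> np.ndarray:
    """Row-stochastic (N+1)x(N+1) matrix of the single-clone chain."""
    r_up, r_down = transition_rate_tables(params)
    N = params.N
    P = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        P[n, n] = 1.0 - r_up[n] - r_down[n]
        if n < N:
            P[n, n + 1] = r_up[n]
        if n > 0:
            P[n, n - 1] = r_down[n]
    return P


def stationary_by_eigenvector(params: ModelParams) -> np.ndarray:
    """Stationary pmf from the left null space of P - I (dense)."""
    P = dense_transition_matrix(params)
    A = P.T - np.eye(P.shape[0])
    # replace one equation by the normalization constraint
    A[-1, :] = 1.0
    b = np.zeros(P.shape[0])
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    return pi


def absorbing_split_and_time(
    params: ModelParams, lo: int, hi: int, start: int, target: int
) -> tuple[float, float]:
    """Splitting probability and conditional expected absorption time.

    Chain restricted to {lo..hi} with absorbing walls at lo and hi.
    Returns (P(absorb at target | start), E[steps | absorb at target]),
    computed with the fundamental matrix of the chain conditioned on
    the target (Doob h-transform), a route independent of the
    package's product formulas and X-transform systems.
    """
    r_up, r_down = transition_rate_tables(params)
    interior = np.arange(lo + 1, hi)
    n_int = interior.size
    if n_int == 0:
        return 1.0, 0.0
    Q = np.zeros((n_int, n_int))
    R = np.zeros((n_int, 2))  # columns: absorb at lo, absorb at hi
    for i, s in enumerate(interior):
        Q[i, i] = 1.0 - r_up[s] - r_down[s]
        if i + 1 < n_int:
            Q[i, i + 1] = r_up[s]
        else:
            R[i, 1] += r_up[s]
        if i - 1 >= 0:
            Q[i, i - 1] = r_down[s]
        else:
            R[i, 0] += r_down[s]
    F = np.linalg.inv(np.eye(n_int) - Q)
    B = F @ R
    col = 1 if target == hi else 0
    b = B[:, col]
    i0 = int(np.flatnonzero(interior == start)[0])
    # Doob transform: conditioned interior chain, then expected steps
    Qc = Q * b[None, :] / b[:, None]
    Fc = np.linalg.inv(np.eye(n_int) - Qc)
    t = Fc @ np.ones(n_int)
    return float(b[i0]), float(t[i0])


def burst_quantities(params: ModelParams, H: int) -> tuple[float, float]:
    """(P_gen(H), T_gen(H)) via the absorbing-chain oracle."""
    r_up, _ = transition_rate_tables(params)
    if H > 1:
        pf, tf = absorbing_split_and_time(params, 0, H, 1, H)
    else:
        pf, tf = 1.0, 0.0
    pb, tb = absorbing_split_and_time(params, 0, H + 1, H, 0)
    return r_up[0] * pf * pb, 1.0 / r_up[0] + tf + tb


def reference_detect_bursts(series) -> list[tuple[int, int, int, int]]:
    """Straight-line reference burst scanner.

    Returns (start, depart, end, height) per completed burst, with the
    same conventions as the package detector but written as the obvious
    sequential scan.
    """
    arr = np.asarray(series, dtype=int)
    out = []
    start, depart = 0, 0
    in_exc = arr[0] > 0
    peak = int(arr[0])
    for i in range(1, arr.size):
        v = int(arr[i])
        if in_exc:
            peak = max(peak, v)
            if v == 0:
                out.append((start, depart, i, peak))
                in_exc = False
                start = i
        elif v > 0:
            in_exc = True
            peak = v
            depart = i
    return out
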