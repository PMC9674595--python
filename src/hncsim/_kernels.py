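"""Compiled inner loops (numba).

All hot loops live here so that the public modules stay readable.
Each kernel receives plain arrays and scalars; parameter validation and
bookkeeping happen in the callers.  Kernels seed numba's own RNG, so a
given (arguments, seed) pair is fully reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "multiclone_record",
    "multiclone_focal_series",
    "monoclonal_fractions",
    "birth_death_series",
    "birth_death_checkpoints",
    "birth_death_ensemble",
    "shannon_snapshots",
]


@njit(cache=True)
def _step(counts, eps, lam, N, tot):
    """One loss + compensation event, in place.  O(K) categorical draws."""
    K = counts.shape[0]
    u = np.random.random() * N
    acc = 0.0
    loss = K - 1
    for k in range(K):
        acc += counts[k]
        if u < acc:
            loss = k
            break
    if lam == 0.0:
        # supply-only: every clone's master has equal weight eps
        comp = int(np.random.random() * K)
        if comp == K:
            comp = K - 1
    else:
        u = np.random.random() * tot
        acc = 0.0
        comp = K - 1
        for k in range(K):
            acc += lam * counts[k] + eps
            if u < acc:
                comp = k
                break
    counts[loss] -= 1
    counts[comp] += 1


@njit(cache=True)
def multiclone_record(counts0, eps, lam, record_steps, seed):
    """Run the multi-clone process, snapshotting at ``record_steps``.

    ``record_steps`` must be sorted, start at 0 and be unique.
    Returns an (n_records, K) int64 array of clone-count snapshots.
    """
    np.random.seed(seed)
    K = counts0.shape[0]
    N = 0
    for k in range(K):
        N += counts0[k]
    tot = lam * N + eps * K
    counts = counts0.copy()
    out = np.empty((record_steps.shape[0], K), dtype=np.int64)
    m = 0
    for i in range(record_steps.shape[0]):
        target = record_steps[i]
        while m < target:
            _step(counts, eps, lam, N, tot)
            m += 1
        out[i] = counts
    return out


@njit(cache=True)
def multiclone_focal_series(counts0, eps, lam, n_steps, seed):
    """Full multi-clone run recording the size of clone 0 at every step.

    Returns an int64 vector of length n_steps + 1 (includes step 0).
    """
    np.random.seed(seed)
    K = counts0.shape[0]
    N = 0
    for k in range(K):
        N += counts0[k]
    tot = lam * N + eps * K
    counts = counts0.copy()
    series = np.empty(n_steps + 1, dtype=np.int64)
    series[0] = counts[0]
    for m in range(n_steps):
        _step(counts, eps, lam, N, tot)
        series[m + 1] = counts[0]
    return series


@njit(cache=True)
def monoclonal_fractions(counts0, eps, lam, checkpoints, n_reps, seed):
    """Fraction of replicates with some n_k = N at each checkpoint step.

    Monoclonality is an instantaneous property: in the hNC model a state
    can leave it again, so each checkpoint is evaluated on the state at
    that step.  When eps == 0 a monoclonal state is absorbing and the
    remaining checkpoints are filled without further simulation.
    Replicate r uses seed + r.
    """
    K = counts0.shape[0]
    N = 0
    for k in range(K):
        N += counts0[k]
    tot = lam * N + eps * K
    n_chk = checkpoints.shape[0]
    hits = np.zeros(n_chk, dtype=np.int64)
    for r in range(n_reps):
        np.random.seed(seed + r)
        counts = counts0.copy()
        m = 0
        absorbed = False
        for i in range(n_chk):
            if not absorbed:
                target = checkpoints[i]
                while m < target:
                    _step(counts, eps, lam, N, tot)
                    m += 1
                    if eps == 0.0:
                        for k in range(K):
                            if counts[k] == N:
                                absorbed = True
                                break
                        if absorbed:
                            break
            mono = absorbed
            if not mono:
                for k in range(K):
                    if counts[k] == N:
                        mono = True
                        break
            if mono:
                hits[i] += 1
    return hits / n_reps


@njit(cache=True)
def birth_death_series(n0, r_up, r_down, n_steps, seed):
    """Single-clone birth-death chain; full event-clock series (int32)."""
    np.random.seed(seed)
    series = np.empty(n_steps + 1, dtype=np.int32)
    n = n0
    series[0] = n
    for m in range(n_steps):
        u = np.random.random()
        if u < r_up[n]:
            n += 1
        elif u < r_up[n] + r_down[n]:
            n -= 1
        series[m + 1] = n
    return series


@njit(cache=True)
def birth_death_checkpoints(n0, r_up, r_down, record_steps, seed):
    """Single-clone chain sampled at the given sorted steps (step 0 allowed)."""
    np.random.seed(seed)
    out = np.empty(record_steps.shape[0], dtype=np.int64)
    n = n0
    m = 0
    for i in range(record_steps.shape[0]):
        target = record_steps[i]
        while m < target:
            u = np.random.random()
            if u < r_up[n]:
                n += 1
            elif u < r_up[n] + r_down[n]:
                n -= 1
            m += 1
        out[i] = n
    return out


@njit(cache=True)
def birth_death_ensemble(n0s, r_up_a, r_down_a, table_idx, record_steps, seed):
    """Ensemble of independent chains with per-replicate rate tables.

    ``table_idx[r]`` selects row r_up_a[table_idx[r]] / r_down_a[...] so
    replicates with different label origins (master vs competitive) can
    share one call.  Replicate r uses seed + r.  Returns
    (n_reps, n_records) int64 sizes.
    """
    n_reps = n0s.shape[0]
    out = np.empty((n_reps, record_steps.shape[0]), dtype=np.int64)
    for r in range(n_reps):
        np.random.seed(seed + r)
        r_up = r_up_a[table_idx[r]]
        r_down = r_down_a[table_idx[r]]
        n = n0s[r]
        m = 0
        for i in range(record_steps.shape[0]):
            target = record_steps[i]
            while m < target:
                u = np.random.random()
                if u < r_up[n]:
                    n += 1
                elif u < r_up[n] + r_down[n]:
                    n -= 1
                m += 1
            out[r, i] = n
    return out


@njit(cache=True)
def shannon_snapshots(counts0, eps, lam, burn_in, n_snapshots, thin, seed):
    """Shannon index of clone fractions at thinned post-burn-in snapshots."""
    np.random.seed(seed)
    K = counts0.shape[0]
    N = 0
    for k in range(K):
        N += counts0[k]
    tot = lam * N + eps * K
    counts = counts0.copy()
    for _ in range(burn_in):
        _step(counts, eps, lam, N, tot)
    out = np.empty(n_snapshots)
    for s in range(n_snapshots):
        for _ in range(thin):
            _step(counts, eps, lam, N, tot)
        h = 0.0
        for k in range(K):
            if counts[k] > 0:
                p = counts[k] / N
                h -= p * np.log(p)
        out[s] = h
    return out
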