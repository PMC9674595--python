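"""Stochastic simulation of the multi-clone Moran process.

Each elementary step pairs a loss event (one of the N competitive cells
differentiates, chosen uniformly: clone k with probability n_k / N) with
a compensation event (clone k refills the slot with probability
(lam*n_k + epsilon) / (lam*N + epsilon*K)).  Both draws are made
independently on the pre-removal state; drawing the same clone twice
leaves the state unchanged.  The open-layer total N is conserved
exactly at every step.

Pulse labeling uses an exact marginalization: because cells within a
clone are exchangeable, the count of labeled competitive cells is
itself a birth-death chain whose supply term is epsilon when the label
sits in a master cell and zero when it marks a competitive-cell
sub-lineage.  Ensembles therefore run as scalar chains, which is what
makes 10^5-replicate labeling experiments cheap; the equivalence with
the full multi-clone bookkeeping is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .exceptions import DomainError, StateError
from .model import ModelParams, steps_to_time

__all__ = [
    "uniform_state",
    "validate_state",
    "Trajectory",
    "LabeledCloneEnsemble",
    "simulate",
    "simulate_single_clone",
    "monoclonal_probability",
    "simulate_pulse_label",
]


def uniform_state(params: ModelParams) -> np.ndarray:
    """Even initial condition: n_k = N/K, largest-remainder rounding.

    When K divides N every clone starts at exactly N/K (the condition
    used for all stationary-regime experiments); otherwise the first
    N mod K clones carry one extra cell.
    """
    base, rem = divmod(params.N, params.K)
    counts = np.full(params.K, base, dtype=np.int64)
    counts[:rem] += 1
    return counts


def validate_state(params: ModelParams, counts: np.ndarray) -> np.ndarray:
    """Check a clone-count vector against the model invariants."""
    arr = np.asarray(counts, dtype=np.int64)
    if arr.shape != (params.K,):
        raise StateError(f"state must have length K={params.K}, got shape {arr.shape}")
    if np.any(arr < 0):
        raise StateError("clone counts must be non-negative")
    if arr.sum() != params.N:
        raise StateError(f"clone counts must sum to N={params.N}, got {int(arr.sum())}")
    return arr


def _record_steps(n_steps: int, record_every: int) -> np.ndarray:
    if n_steps < 0:
        raise DomainError("n_steps must be >= 0")
    if record_every < 1:
        raise DomainError("record_every must be >= 1")
    steps = np.arange(0, n_steps + 1, record_every, dtype=np.int64)
    if steps[-1] != n_steps:
        steps = np.append(steps, n_steps)
    return steps


@dataclass
class Trajectory:
    """Recorded multi-clone trajectory.

    ``states[i, k]`` is the size of clone k at step ``record_steps[i]``;
    ``times`` is the calibrated-time axis ``record_steps / (lam*N + eps*K)``.
    """

    params: ModelParams
    record_steps: np.ndarray
    times: np.ndarray
    states: np.ndarray
    seed: int

    def clone_series(self, k: int) -> np.ndarray:
        return self.states[:, k]

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (step, clone)."""
        R, K = self.states.shape
        return pd.DataFrame(
            {
                "step": np.repeat(self.record_steps, K),
                "time": np.repeat(self.times, K),
                "clone": np.tile(np.arange(K), R),
                "size": self.states.ravel(),
            }
        )

    def to_wide(self) -> pd.DataFrame:
        """Wide format: clones as rows, recorded times as columns."""
        return pd.DataFrame(
            self.states.T,
            index=[f"clone_{k:03d}" for k in range(self.states.shape[1])],
            columns=self.times,
        )


@dataclass
class LabeledCloneEnsemble:
    """Replicate labeled-clone size series from a pulse-labeling run.

    ``sizes[r, i]`` is the number of labeled competitive cells in
    replicate r at step ``record_steps[i]``; ``master_origin[r]`` says
    whether the label landed in a master cell (True) or marked a
    competitive-cell sub-lineage (False).
    """

    params: ModelParams
    record_steps: np.ndarray
    times: np.ndarray
    sizes: np.ndarray
    master_origin: np.ndarray
    seed: int

    def sizes_at(self, step: int) -> np.ndarray:
        """Labeled-clone sizes across replicates at a recorded step."""
        idx = np.flatnonzero(self.record_steps == step)
        if idx.size == 0:
            raise DomainError(
                f"step {step} was not recorded; available: {self.record_steps.tolist()}"
            )
        return self.sizes[:, idx[0]]

    def to_tidy(self) -> pd.DataFrame:
        R, T = self.sizes.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(R), T),
                "step": np.tile(self.record_steps, R),
                "time": np.tile(self.times, R),
                "size": self.sizes.ravel(),
                "master_origin": np.repeat(self.master_origin, T),
            }
        )


def simulate(
    params: ModelParams,
    init: Optional[np.ndarray] = None,
    n_steps: int = 0,
    seed: int = 0,
    record_every: int = 1,
) -> Trajectory:
    """Simulate the multi-clone process for ``n_steps`` elementary steps.

    Snapshots are stored every ``record_every`` steps, always including
    step 0 and step ``n_steps``.  Identical arguments give identical
    trajectories.
    """
    counts0 = uniform_state(params) if init is None else validate_state(params, init)
    steps = _record_steps(n_steps, record_every)
    states = _kernels.multiclone_record(
        counts0, params.epsilon, params.lam, steps, seed
    )
    return Trajectory(
        params=params,
        record_steps=steps,
        times=steps_to_time(params, steps),
        states=states,
        seed=seed,
    )


def simulate_single_clone(
    params: ModelParams, n0: int, n_steps: int, seed: int = 0
) -> np.ndarray:
    """Event-clock series of one clone under its marginal birth-death chain.

    The marginal dynamics of a single clone in the multi-clone process
    is exactly the chain with rates r_up / r_down, so long single-clone
    runs (burst censuses, stationary histograms) avoid the O(K) cost of
    the full state.  Returns an int32 vector of length ``n_steps + 1``.
    """
    if not 0 <= n0 <= params.N:
        raise DomainError(f"n0 must lie in [0, {params.N}]")
    from .model import transition_rate_tables

    r_up, r_down = transition_rate_tables(params)
    return _kernels.birth_death_series(n0, r_up, r_down, n_steps, seed)


def monoclonal_probability(
    params: ModelParams,
    init: Optional[np.ndarray] = None,
    checkpoints: Sequence[int] = (),
    n_reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of replicates monoclonal (some n_k = N) at each checkpoint.

    Monoclonality is evaluated instantaneously at each checkpoint step;
    in the hNC model a replicate can be monoclonal at one checkpoint and
    polyclonal again at the next.  Standard binomial Monte-Carlo error
    applies to the returned fractions.
    """
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    chk = np.asarray(sorted(checkpoints), dtype=np.int64)
    if chk.size == 0:
        raise DomainError("at least one checkpoint step is required")
    if chk[0] < 0:
        raise DomainError("checkpoints must be >= 0")
    counts0 = uniform_state(params) if init is None else validate_state(params, init)
    return _kernels.monoclonal_fractions(
        counts0, params.epsilon, params.lam, chk, n_reps, seed
    )


def _label_rate_tables(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Birth-death tables for the labeled-cell count, per label origin.

    Row 0: label in a master cell (supply epsilon feeds the label).
    Row 1: label marking a competitive sub-lineage (no supply).
    """
    n = np.arange(params.N + 1, dtype=float)
    tot = params.total_rate
    r_up = np.empty((2, params.N + 1))
    r_down = np.empty((2, params.N + 1))
    for row, eps_label in enumerate((params.epsilon, 0.0)):
        q = (params.lam * n + eps_label) / tot
        r_up[row] = q * (1.0 - n / params.N)
        r_down[row] = (1.0 - q) * (n / params.N)
    return r_up, r_down


def simulate_pulse_label(
    params: ModelParams,
    n_steps: int,
    n_reps: int,
    seed: int = 0,
    record_at: Optional[Sequence[int]] = None,
) -> LabeledCloneEnsemble:
    """Pulse-labeling experiment: label one random cell, track its clone.

    Per replicate one cell is drawn uniformly from the K + N master and
    competitive cells.  A labeled master starts with zero labeled
    competitive cells and marks every cell it subsequently supplies; a
    labeled competitive cell starts the labeled clone at size one and
    marks its symmetric-division descendants.  The labeled competitive
    count evolves as the exact marginal birth-death chain described in
    the module docstring, so its law does not depend on the background
    clone configuration and no burn-in is required.
    """
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if record_at is None:
        record_at = [n_steps]
    steps = np.asarray(sorted(record_at), dtype=np.int64)
    if steps[0] < 0 or steps[-1] > n_steps:
        raise DomainError("record_at steps must lie in [0, n_steps]")

    rng = np.random.default_rng(seed)
    master = rng.random(n_reps) < params.K / (params.K + params.N)
    table_idx = np.where(master, 0, 1).astype(np.int64)
    n0s = np.where(master, 0, 1).astype(np.int64)

    r_up, r_down = _label_rate_tables(params)
    sizes = _kernels.birth_death_ensemble(n0s, r_up, r_down, table_idx, steps, seed)
    return LabeledCloneEnsemble(
        params=params,
        record_steps=steps,
        times=steps_to_time(params, steps),
        sizes=sizes,
        master_origin=master,
        seed=seed,
    )
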