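"""Clone-count tables: readers, writers, sorting and the fixture generator.

The canonical on-disk layout mirrors published clonal-tracking tables:
wide CSV, UTF-8, first column ``clone`` holding the clone identifier,
remaining column headers numeric timepoints (months by default).  A
tidy long-format writer is also provided.  Real tables may carry
non-integer frequencies, so empirical validation only enforces
non-negativity; fixtures written by :func:`generate_fixture` are
integer counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError, DomainError
from .model import ModelParams
from .simulate import simulate, uniform_state

__all__ = [
    "CloneMatrix",
    "read_clone_matrix",
    "write_clone_matrix",
    "write_tidy",
    "sort_clones_by_peak",
    "generate_fixture",
]

logger = logging.getLogger("hncsim")


@dataclass
class CloneMatrix:
    """Clone x timepoint count table.

    ``counts[i, j]`` is the abundance of ``clones[i]`` at
    ``timepoints[j]``; timepoints are strictly increasing and labeled
    with ``time_unit``.
    """

    clones: list[str]
    timepoints: np.ndarray
    counts: np.ndarray
    time_unit: str = "months"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.clones) < 1:
            raise DataError("a clone matrix needs at least one clone")
        if len(set(self.clones)) != len(self.clones):
            dupes = sorted({c for c in self.clones if self.clones.count(c) > 1})
            raise DataError(f"duplicate clone ids: {dupes}")
        if self.counts.shape != (len(self.clones), self.timepoints.size):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.clones)} clones x {self.timepoints.size} timepoints"
            )
        if np.any(self.counts < 0):
            raise DataError("negative counts are not allowed")
        if self.timepoints.size > 1 and np.any(np.diff(self.timepoints) <= 0):
            raise DataError("timepoints must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.timepoints)
        df.insert(0, "clone", self.clones)
        return df

    def fractions(self, timepoint_index: Optional[int] = None) -> np.ndarray:
        """Clone fractions at one timepoint, or pooled over all of them."""
        col = (
            self.counts.sum(axis=1)
            if timepoint_index is None
            else self.counts[:, timepoint_index]
        )
        total = col.sum()
        if total <= 0:
            raise DataError("cannot compute fractions from an all-zero column")
        return col / total


def read_clone_matrix(
    path: Union[str, Path], dialect: Optional[str] = None
) -> CloneMatrix:
    """Read a wide clone x timepoint table (CSV or TSV).

    ``dialect`` forces ``"csv"`` or ``"tsv"``; by default the extension
    decides (``.tsv``/``.tab`` -> tab, else comma).  Missing cells are
    filled with 0 (logged); malformed headers, duplicate clone ids and
    negative counts raise :class:`DataError` with line numbers where
    possible.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a clone column plus >= 1 timepoint column")
    first = df.columns[0]
    if first.lower() != "clone":
        raise DataError(f"{path}: first column header must be 'clone', got {first!r}")
    try:
        timepoints = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric timepoint header: {exc}") from exc

    clones = df[first].tolist()
    dupes = df[first][df[first].duplicated()].tolist()
    if dupes:
        lines = [int(i) + 2 for i in df.index[df[first].duplicated(keep=False)]]
        raise DataError(f"{path}: duplicate clone ids {sorted(set(dupes))} at lines {lines}")

    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing cells filled with 0", path, n_missing)
        values = values.fillna(0.0)
    counts = values.to_numpy()
    neg = np.argwhere(counts < 0)
    if neg.size:
        i, j = neg[0]
        raise DataError(
            f"{path}: negative count at line {int(i) + 2}, "
            f"timepoint {timepoints[j]!r}"
        )
    return CloneMatrix(clones=clones, timepoints=timepoints, counts=counts)


def write_clone_matrix(matrix: CloneMatrix, path: Union[str, Path]) -> None:
    """Write the canonical wide CSV (or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = matrix.to_frame()
    # Integer-valued tables round-trip bit-identically as integers.
    if np.allclose(matrix.counts, np.round(matrix.counts)):
        for c in df.columns[1:]:
            df[c] = df[c].astype(np.int64)
    df.columns = ["clone"] + [format(t, "g") for t in matrix.timepoints]
    df.to_csv(path, sep=sep, index=False)


def write_tidy(matrix: CloneMatrix, path: Union[str, Path]) -> None:
    """Write the long format: columns clone, time, count."""
    n_c, n_t = matrix.counts.shape
    pd.DataFrame(
        {
            "clone": np.repeat(matrix.clones, n_t),
            "time": np.tile(matrix.timepoints, n_c),
            "count": matrix.counts.ravel(),
        }
    ).to_csv(path, index=False)


def sort_clones_by_peak(matrix: CloneMatrix) -> list[str]:
    """Clone ids ordered by the timepoint of each clone's maximum count.

    Ties within a clone (several equal maxima) resolve to the earliest
    such timepoint; clones peaking at the same timepoint keep input
    order (stable sort).  This is the ordering used for staircase-style
    clonal-tracking heatmaps.
    """
    peak_idx = np.argmax(matrix.counts, axis=1)  # argmax takes the earliest max
    order = np.argsort(peak_idx, kind="stable")
    return [matrix.clones[i] for i in order]


def generate_fixture(
    params: ModelParams,
    months: int,
    steps_per_month: int = 1000,
    seed: int = 0,
    sampling_noise: bool = False,
    sample_size: int = 1000,
    init: Optional[np.ndarray] = None,
) -> CloneMatrix:
    """Synthetic clonal-tracking table with the model's statistical structure.

    Runs the multi-clone simulation from the uniform initial state and
    samples every clone's size once per "month" of ``steps_per_month``
    steps, labeling columns 1..months.  With ``sampling_noise`` each
    column is replaced by a multinomial draw of ``sample_size`` cells
    from the clone fractions, emulating blood-draw subsampling.
    Deterministic given the seed.  This synthetic table stands in for
    downloaded clonal-tracking datasets in all tests and examples.
    """
    if months < 1:
        raise DomainError("months must be >= 1")
    if steps_per_month < 1:
        raise DomainError("steps_per_month must be >= 1")
    logger.info(
        "generate_fixture: K=%d N=%d epsilon=%g lambda=%g months=%d "
        "steps_per_month=%d seed=%d sampling_noise=%s",
        params.K, params.N, params.epsilon, params.lam,
        months, steps_per_month, seed, sampling_noise,
    )
    traj = simulate(
        params,
        init=init if init is not None else uniform_state(params),
        n_steps=months * steps_per_month,
        seed=seed,
        record_every=steps_per_month,
    )
    counts = traj.states[1:].T  # drop the artificial uniform state at step 0
    if sampling_noise:
        rng = np.random.default_rng(seed)
        sampled = np.empty_like(counts)
        for j in range(counts.shape[1]):
            sampled[:, j] = rng.multinomial(sample_size, counts[:, j] / params.N)
        counts = sampled
    return CloneMatrix(
        clones=[f"clone_{k:03d}" for k in range(params.K)],
        timepoints=np.arange(1, months + 1, dtype=float),
        counts=counts,
    )
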