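"""Core model parameters and the single-clone transition kernel.

The model is a discrete-step Moran process with two compartments: a
*closed layer* of ``K`` master stem cells (one per clone, protected from
competition, each supplying new cells at rate ``epsilon``) and an *open
layer* of ``N`` competitive stem cells (lost at random and replaced
either by symmetric division of a competitive cell, rate ``lam`` per
cell, or by supply from a master cell).

Tracking a single focal clone, each elementary step changes its size
``n`` by at most one, with probabilities

    r_up(n)   = (epsilon + lam*n) / (epsilon*K + lam*N) * (1 - n/N)
    r_down(n) = (1 - (epsilon + lam*n) / (epsilon*K + lam*N)) * n/N

and the remaining mass is the no-change probability.  These two
functions are the probabilistic heart of every other module: the full
multi-clone simulator, the master-equation/stationary analytics and the
first-passage burst theory all reduce to them.

Setting ``lam = 0`` recovers the purely hierarchical model (supply
only), ``epsilon = 0`` the neutral-competition (NC) model (drift only),
and both positive the hierarchical-neutral-competition (hNC) model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = [
    "ModelParams",
    "TransitionRates",
    "transition_up",
    "transition_down",
    "transition_rates",
    "transition_rate_tables",
    "steps_to_time",
    "classify_regime",
]

#: Regime labels, keyed by (epsilon > 0, lam > 0).
_REGIMES = {
    (True, False): "hierarchical",
    (False, True): "NC",
    (True, True): "hNC",
}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-layer Moran model.

    Parameters
    ----------
    K : int
        Number of master stem cells (= number of clone labels), >= 1.
    N : int
        Number of competitive stem cells in the open layer, >= 1.
    epsilon : float
        Proliferation (supply) rate of each master stem cell, >= 0.
    lam : float
        Proliferation rate of each competitive stem cell, >= 0.
        Defaults to 1, the reference scale: only the ratio epsilon/lam
        matters for the embedded chain, while calibrated time carries
        the absolute rates through ``lam*N + epsilon*K``.
    """

    K: int
    N: int
    epsilon: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ParameterError(f"K must be a positive integer, got {self.K!r}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ParameterError(f"N must be a positive integer, got {self.N!r}")
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ParameterError(f"epsilon must be finite and >= 0, got {self.epsilon!r}")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ParameterError(f"lam must be finite and >= 0, got {self.lam!r}")
        if self.epsilon == 0 and self.lam == 0:
            raise ParameterError(
                "epsilon and lam cannot both be zero: no compensation event exists"
            )
        object.__setattr__(self, "K", int(self.K))
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "epsilon", float(self.epsilon))
        object.__setattr__(self, "lam", float(self.lam))

    @property
    def total_rate(self) -> float:
        """Normalizing rate ``lam*N + epsilon*K`` (> 0 for valid params)."""
        return self.lam * self.N + self.epsilon * self.K

    @property
    def regime(self) -> str:
        """One of ``"hierarchical"``, ``"NC"``, ``"hNC"``."""
        return _REGIMES[(self.epsilon > 0, self.lam > 0)]

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        """Serialize to a flat JSON object with keys K, N, epsilon, lambda."""
        return json.dumps(
            {"K": self.K, "N": self.N, "epsilon": self.epsilon, "lambda": self.lam}
        )

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "ModelParams":
        """Deserialize from a JSON string, file path or already-parsed dict."""
        if isinstance(source, dict):
            obj = source
        else:
            text = str(source)
            p = Path(text)
            if p.suffix.lower() == ".json" and p.exists():
                text = p.read_text()
            obj = json.loads(text)
        return cls(
            K=obj["K"], N=obj["N"], epsilon=obj["epsilon"],
            lam=obj.get("lambda", obj.get("lam", 1.0)),
        )


@dataclass(frozen=True)
class TransitionRates:
    """Per-step up/down probabilities of the focal clone at size ``n``."""

    r_up: float
    r_down: float
    n: int


def _check_n(params: ModelParams, n) -> np.ndarray:
    arr = np.asarray(n)
    if np.any(arr < 0) or np.any(arr > params.N):
        raise DomainError(f"clone size n must lie in [0, {params.N}], got {n!r}")
    return arr


def transition_up(params: ModelParams, n):
    """Probability that the focal clone grows by one in a step.

    Accepts a scalar or array clone size ``n`` in ``[0, N]``.
    """
    arr = _check_n(params, n)
    tot = params.total_rate
    if tot == 0:  # unreachable for validated params, kept as a guard
        raise ParameterError("epsilon*K + lam*N must be positive")
    val = (params.epsilon + params.lam * arr) / tot * (1.0 - arr / params.N)
    return float(val) if np.isscalar(n) or arr.ndim == 0 else val


def transition_down(params: ModelParams, n):
    """Probability that the focal clone shrinks by one in a step."""
    arr = _check_n(params, n)
    tot = params.total_rate
    if tot == 0:
        raise ParameterError("epsilon*K + lam*N must be positive")
    val = (1.0 - (params.epsilon + params.lam * arr) / tot) * (arr / params.N)
    return float(val) if np.isscalar(n) or arr.ndim == 0 else val


def transition_rates(params: ModelParams, n: int) -> TransitionRates:
    """Both one-step probabilities at clone size ``n``, as a record."""
    return TransitionRates(
        r_up=transition_up(params, n), r_down=transition_down(params, n), n=int(n)
    )


def transition_rate_tables(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectors ``(r_up, r_down)`` over the whole lattice n = 0..N.

    Shared precomputation for the analytics modules and the compiled
    single-clone simulation kernels.
    """
    n = np.arange(params.N + 1)
    return transition_up(params, n), transition_down(params, n)


def steps_to_time(params: ModelParams, m) -> Union[float, np.ndarray]:
    """Calibrated time of step ``m``: ``t = m / (lam*N + epsilon*K)``.

    One unit of calibrated time is the expected interval per elementary
    replacement event, so models with different rate parameters are
    comparable on the same clock.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0):
        raise DomainError("step count m must be >= 0")
    tot = params.total_rate
    if tot == 0:
        raise ParameterError("lam*N + epsilon*K must be positive")
    val = arr / tot
    return float(val) if np.isscalar(m) or arr.ndim == 0 else val


def classify_regime(params: ModelParams) -> str:
    """Classify parameters as ``hierarchical`` (lam=0), ``NC`` (epsilon=0) or ``hNC``."""
    return params.regime
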