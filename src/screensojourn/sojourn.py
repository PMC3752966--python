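"""Sojourn-time distributions.

The sojourn time ``Y`` is the duration of the preclinical detectable
phase.  All closed-form estimators and the maximum-likelihood fit assume
an exponential distribution with mean ``mu`` (density
``f(y) = (1/mu) * exp(-y/mu)``), the conventional choice in screening
models; the numeric utilities (Volterra solver, simulator) accept any
object with the same small interface so other families can be explored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["ExponentialSojourn", "SojournDistribution"]


@runtime_checkable
class SojournDistribution(Protocol):
    """Minimal interface required of a sojourn-time distribution."""

    def density(self, y): ...

    def survival(self, y): ...

    def moment(self, k: int) -> float: ...

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray: ...


def _check_nonnegative(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("sojourn times are nonnegative; got a negative y")
    return arr


@dataclass(frozen=True)
class ExponentialSojourn:
    """Exponential sojourn time with mean ``mu`` (years)."""

    mu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0):
            raise ValueError(f"mu must be positive, got {self.mu}")

    def density(self, y):
        """Density ``f(y) = (1/mu) exp(-y/mu)`` for ``y >= 0``."""
        arr = _check_nonnegative(y)
        out = np.exp(-arr / self.mu) / self.mu
        return out if out.ndim else float(out)

    def survival(self, y):
        """Survival ``Pr(Y >= y) = exp(-y/mu)`` for ``y >= 0``."""
        arr = _check_nonnegative(y)
        out = np.exp(-arr / self.mu)
        return out if out.ndim else float(out)

    def moment(self, k: int) -> float:
        """Raw moment ``E(Y^k) = k! * mu**k`` for integer ``k >= 1``."""
        if not isinstance(k, (int, np.integer)) or k < 1:
            raise ValueError(f"moment order must be a positive integer, got {k}")
        return math.factorial(int(k)) * self.mu ** int(k)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.exponential(self.mu, size=size)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": "exponential", "mu": self.mu}

    @classmethod
    def from_dict(cls, d: dict) -> "ExponentialSojourn":
        if d.get("family", "exponential") != "exponential":
            raise ValueError(f"unsupported sojourn family {d.get('family')!r}")
        return cls(mu=float(d["mu"]))
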