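"""Background clinical incidence and preclinical (onset) incidence.

Clinical incidence is modelled as a linear hazard ``I(x) = beta1 + beta2*x``
in time since study entry, i.e. a quadratic cumulative incidence
``C(x) = beta1*x + (beta2/2)*x**2``.  This is the standard local
approximation for prostate-cancer incidence over a screening-trial
follow-up window, with ``beta1`` the hazard at entry (cases per
person-year) and ``beta2`` the linear trend (per person-year per year).

Onset incidence ``I_o`` is the rate of entry into the preclinical
detectable phase.  It is linked to clinical incidence by convolution with
the sojourn-time density,

    I(x) = integral_0^inf I_o(x - y) f(y) dy,

a Volterra equation of the first kind.  For an exponential sojourn time
with mean ``mu`` the deconvolution has the closed form
``I_o(x) = I(x) + mu * I'(x) = beta1 + beta2*(x + mu)``; for general
densities :func:`solve_volterra_onset` solves the discretized equation by
product integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "DomainError",
    "QuadraticIncidenceModel",
    "incidence_at",
    "cumulative_incidence",
    "onset_incidence_exponential",
    "solve_volterra_onset",
    "VolterraSolution",
]


class DomainError(ValueError):
    """Evaluation outside the validity domain of an incidence model."""


@dataclass(frozen=True)
class QuadraticIncidenceModel:
    """Linear clinical hazard ``I(x) = beta1 + beta2*x``.

    Parameters
    ----------
    beta1 : float
        Hazard at the time origin, in cases per person-year.  Must be
        nonnegative.
    beta2 : float
        Linear trend of the hazard, per person-year per year.  May be
        negative, but evaluation is only allowed where ``I(x) >= 0``.
    t_origin : float
        Time origin (years); study entry and first screen throughout.
    x_max : float
        Upper bound (exclusive) of the validity window, in years.  The
        quadratic is a local fit; extrapolation past the fitted window is
        refused rather than clamped.
    """

    beta1: float
    beta2: float
    t_origin: float = 0.0
    x_max: float = math.inf

    def __post_init__(self) -> None:
        if not (self.beta1 >= 0.0):
            raise ValueError(f"beta1 must be nonnegative, got {self.beta1}")
        if self.x_max <= self.x_min:
            raise ValueError("empty validity domain: x_max <= positivity bound")

    @property
    def x_min(self) -> float:
        """Lower edge of the validity domain (hazard positivity bound)."""
        if self.beta2 > 0.0:
            return self.t_origin - self.beta1 / self.beta2
        return -math.inf

    def _check_domain(self, x: float) -> None:
        if x < self.x_min or x >= self.x_max:
            raise DomainError(
                f"x={x} outside incidence domain [{self.x_min}, {self.x_max})"
            )

    def rate(self, x: float) -> float:
        """Clinical incidence ``I(x)`` at time ``x`` (per person-year)."""
        self._check_domain(x)
        return self.beta1 + self.beta2 * (x - self.t_origin)

    def cumulative(self, x: float) -> float:
        """Cumulative incidence ``C(x) = beta1*x + (beta2/2)*x**2``.

        ``x`` is measured from the time origin and must be nonnegative.
        """
        if x < self.t_origin:
            raise DomainError(f"cumulative incidence needs x >= {self.t_origin}")
        if x >= self.x_max:
            raise DomainError(f"x={x} outside incidence domain (x_max={self.x_max})")
        u = x - self.t_origin
        return self.beta1 * u + 0.5 * self.beta2 * u * u

    def onset_rate_exponential(self, mu: float, x: float) -> float:
        """Onset incidence ``I_o(x) = beta1 + beta2*(x + mu)``.

        Closed-form solution of the deconvolution for an exponential
        sojourn time with mean ``mu``.  Convolving this rate with the
        exponential density reproduces ``I(x)`` exactly.
        """
        if mu < 0.0:
            raise ValueError(f"mu must be nonnegative, got {mu}")
        if x + mu < self.x_min or x >= self.x_max:
            raise DomainError(
                f"x={x} outside onset domain [{self.x_min - mu}, {self.x_max})"
            )
        return self.beta1 + self.beta2 * (x - self.t_origin + mu)

    def onset_positivity_bound(self, mu: float) -> float:
        """Time below which the exponential-sojourn onset rate is negative."""
        return self.x_min - mu

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "beta2": self.beta2,
            "t_origin": self.t_origin,
            "x_max": None if math.isinf(self.x_max) else self.x_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticIncidenceModel":
        x_max = d.get("x_max")
        return cls(
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
            t_origin=float(d.get("t_origin", 0.0)),
            x_max=math.inf if x_max is None else float(x_max),
        )


def incidence_at(model: QuadraticIncidenceModel, x: float) -> float:
    """Clinical incidence rate ``I(x)`` (per person-year)."""
    return model.rate(x)


def cumulative_incidence(model: QuadraticIncidenceModel, x: float) -> float:
    """Cumulative clinical incidence ``C(x)`` from the time origin."""
    return model.cumulative(x)


def onset_incidence_exponential(
    model: QuadraticIncidenceModel, mu: float, x: float
) -> float:
    """Onset incidence for an exponential sojourn time with mean ``mu``."""
    return model.onset_rate_exponential(mu, x)


class VolterraSolution(NamedTuple):
    """Discretized onset incidence from :func:`solve_volterra_onset`.

    ``grid`` holds the midpoints of the input grid cells; ``onset`` the
    onset rates at those midpoints.
    """

    grid: np.ndarray
    onset: np.ndarray


def solve_volterra_onset(
    incidence: Callable[[np.ndarray], np.ndarray],
    sojourn_density: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray,
) -> VolterraSolution:
    """Deconvolve clinical incidence into onset incidence on a grid.

    Solves the first-kind Volterra equation
    ``I(x) = integral_{x0}^{x} I_o(u) f(x - u) du`` for ``I_o`` by midpoint
    product integration and forward substitution.  The midpoint rule is
    used because it is stable for first-kind equations (the trapezoid rule
    produces oscillating solutions).  The onset rate is represented at the
    cell midpoints of the supplied uniform grid.

    The truncation of onset at the grid start ``x0`` is exact when the
    supplied incidence vanishes there (e.g. a quadratic cumulative
    incidence with the grid starting at its hazard positivity bound);
    otherwise onset mass from before ``x0`` is folded into the first cells
    and the solution is only trustworthy a few kernel scales into the grid.

    Parameters
    ----------
    incidence : callable
        Vectorized clinical incidence rate over time.
    sojourn_density : callable
        Vectorized sojourn-time density; nonnegative, with enough mass on
        the grid scale that the kernel is invertible.
    grid : array
        Uniform, strictly increasing time grid.

    Returns
    -------
    VolterraSolution
        Midpoint grid and onset rates such that the midpoint quadrature
        convolution of ``onset`` with the density reproduces ``incidence``
        at every grid node.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("grid must be a 1-D array with at least 3 nodes")
    steps = np.diff(grid)
    h = steps[0]
    if h <= 0.0:
        raise ValueError("grid step must be positive")
    if not np.allclose(steps, h, rtol=1e-8, atol=1e-12):
        raise ValueError("grid must be uniform")

    mid = grid[:-1] + 0.5 * h
    n = mid.size
    lags = grid[1:, None] - mid[None, :]  # (n, n); entry (i, j) = x_{i+1} - m_j
    with np.errstate(invalid="ignore"):
        kernel = np.where(lags > 0.0, lags, h / 2.0)
        fvals = sojourn_density(kernel)
    if np.any(fvals < -1e-12):
        raise ValueError("sojourn density must be nonnegative")
    diag = sojourn_density(np.array([h / 2.0]))[0]
    if diag * h <= 1e-300:
        raise ValueError(
            "ill-conditioned kernel: sojourn density carries no mass within "
            "one grid step of zero; refine the grid or rescale the density"
        )
    a = np.tril(h * fvals)
    rhs = np.asarray(incidence(grid[1:]), dtype=float)
    onset = solve_triangular(a, rhs, lower=True)
    return VolterraSolution(grid=mid, onset=onset)
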