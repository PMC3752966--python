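"""Direct (closed-form) mean-sojourn-time estimators.

All four estimators map an estimated prevalence ``P`` of the preclinical
detectable phase — detection rate over sensitivity, ``P = R/s`` — to a
mean sojourn time using the background-incidence model:

* ``catchup_time`` — the catch-up time itself: the time at which
  cumulative incidence reaches ``P`` (positive root of
  ``(beta2/2) m^2 + beta1 m = P``).
* ``catchup_model`` — the moment estimator of the catch-up model with
  exponential sojourn (positive root of ``beta2 mu^2 + beta1 mu = P``).
* ``classic`` — the prevalence/incidence ratio ``P / I(t)`` of the
  classic Markov model with exponential sojourn.
* ``onset_catchup`` — the catch-up time method applied to onset
  incidence, algebraically identical to ``catchup_time``.

With an increasing incidence trend the three distinct estimates are
ordered ``catchup_model < catchup_time < classic``; they coincide when
the trend is zero.  Confidence intervals propagate a normal-approximation
Poisson interval on the screen-detected count through the (monotone)
estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from .incidence import QuadraticIncidenceModel

__all__ = [
    "PrevalenceObservation",
    "DirectEstimate",
    "DIRECT_METHODS",
    "estimate_catchup_time",
    "estimate_mu_catchup_model",
    "estimate_mu_classic",
    "estimate_catchup_time_onset",
    "poisson_ci_direct",
]


@dataclass(frozen=True)
class PrevalenceObservation:
    """First-screen detection data: ``detected`` of ``n_screened`` persons."""

    detected: int
    n_screened: int
    assumed_sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.detected <= self.n_screened):
            raise ValueError("need 0 <= detected <= n_screened")
        if not (0.0 < self.assumed_sensitivity <= 1.0):
            raise ValueError("assumed sensitivity must lie in (0, 1]")

    @property
    def prevalence(self) -> float:
        """Estimated prevalence ``P = R / s``."""
        p = self.detected / (self.n_screened * self.assumed_sensitivity)
        if p > 1.0:
            raise ValueError("detection rate over sensitivity exceeds 1")
        return p


@dataclass(frozen=True)
class DirectEstimate:
    """A direct mean-sojourn-time estimate with its confidence interval."""

    method: str
    mu_hat: float
    ci: tuple[float, float]
    level: float
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.mu_hat <= hi):
            raise ValueError("confidence interval does not bracket the estimate")


def _positive_root(half_quad: float, lin: float, target: float) -> float:
    """Positive root of ``half_quad * m^2 + lin * m - target = 0``.

    ``half_quad >= 0``; the negative root is discarded.  Falls back to the
    linear solution when ``half_quad == 0``.
    """
    if half_quad == 0.0:
        if lin <= 0.0:
            raise ValueError("degenerate incidence: beta1 = beta2 = 0")
        return target / lin
    disc = lin * lin + 4.0 * half_quad * target
    return (-lin + math.sqrt(disc)) / (2.0 * half_quad)


def _check_reachable(model: QuadraticIncidenceModel, P: float) -> None:
    if not (0.0 < P < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {P}")
    if model.beta2 < 0.0:
        raise ValueError("direct estimators require a nondecreasing hazard")
    if math.isfinite(model.x_max):
        cmax = model.cumulative(math.nextafter(model.x_max, model.t_origin))
        if P >= cmax:
            raise ValueError(
                f"prevalence {P} exceeds the maximum attainable cumulative "
                f"incidence {cmax:.6g} on the model domain"
            )


def estimate_catchup_time(model: QuadraticIncidenceModel, P: float) -> float:
    """Catch-up time: solve ``C(m) = P`` for ``m``."""
    _check_reachable(model, P)
    return _positive_root(0.5 * model.beta2, model.beta1, P)


def estimate_mu_catchup_model(model: QuadraticIncidenceModel, P: float) -> float:
    """Catch-up-model moment estimator: solve ``beta1 mu + beta2 mu^2 = P``."""
    _check_reachable(model, P)
    return _positive_root(model.beta2, model.beta1, P)


def estimate_mu_classic(
    model: QuadraticIncidenceModel, P: float, t: float = 0.0
) -> float:
    """Classic prevalence/incidence ratio ``mu = P / I(t)``."""
    if P == 0.0:
        return 0.0
    if not (0.0 < P < 1.0):
        raise ValueError(f"prevalence must lie in [0, 1), got {P}")
    rate = model.rate(t)
    if rate <= 0.0:
        raise ValueError(f"incidence at t={t} must be positive, got {rate}")
    return P / rate


def estimate_catchup_time_onset(
    model: QuadraticIncidenceModel, P: float, method: str = "algebraic"
) -> float:
    """Catch-up time method applied to onset incidence.

    Solves ``integral_{-mu}^{0} I_o(u; mu) du = P`` self-consistently in
    ``mu`` with ``I_o(u; mu) = I(u) + beta2 * mu``.  The integral
    simplifies to ``beta1 mu + (beta2/2) mu^2``, so the estimate equals
    :func:`estimate_catchup_time`; ``method="numeric"`` solves the
    integral equation by quadrature and root bracketing instead.
    """
    _check_reachable(model, P)
    if method == "algebraic":
        return _positive_root(0.5 * model.beta2, model.beta1, P)
    if method == "numeric":

        def gap(mu: float) -> float:
            val, _ = quad(
                lambda u: model.beta1 + model.beta2 * (u - model.t_origin + mu),
                -mu,
                0.0,
            )
            return val - P

        hi = 1.0
        while gap(hi) < 0.0:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("prevalence not reachable by onset catch-up time")
        return brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-14)
    raise ValueError(f"unknown method {method!r}")


DIRECT_METHODS = {
    "catchup_time": lambda model, P, t: estimate_catchup_time(model, P),
    "catchup_model": lambda model, P, t: estimate_mu_catchup_model(model, P),
    "classic": estimate_mu_classic,
    "onset_catchup": lambda model, P, t: estimate_catchup_time_onset(model, P),
}


def poisson_ci_direct(
    model: QuadraticIncidenceModel,
    obs: PrevalenceObservation,
    method: str,
    level: float = 0.95,
    t: float = 0.0,
) -> DirectEstimate:
    """Direct estimate with a propagated Poisson confidence interval.

    The screen-detected count is treated as Poisson; its
    normal-approximation interval ``count +/- z * sqrt(count)`` is
    converted to prevalence bounds and mapped through the chosen
    estimator.  All four estimators are increasing in ``P``, so mapping
    the endpoints is exact.  Background-incidence uncertainty is ignored.
    """
    if method not in DIRECT_METHODS:
        raise ValueError(f"method must be one of {sorted(DIRECT_METHODS)}")
    if obs.detected < 1:
        raise ValueError(
            "normal-approximation Poisson interval needs at least one detected case"
        )
    if not (0.0 <= level < 1.0):
        raise ValueError(f"confidence level must lie in [0, 1), got {level}")
    est = DIRECT_METHODS[method]
    z = float(norm.ppf(0.5 + level / 2.0))
    denom = obs.n_screened * obs.assumed_sensitivity
    half = z * math.sqrt(obs.detected)
    p_lo = (obs.detected - half) / denom
    p_hi = (obs.detected + half) / denom
    if p_lo <= 0.0:
        raise ValueError(
            "lower Poisson bound is nonpositive; the normal approximation "
            "is unusable at this count"
        )
    return DirectEstimate(
        method=method,
        mu_hat=est(model, obs.prevalence, t),
        ci=(est(model, p_lo, t), est(model, p_hi, t)),
        level=level,
        inputs={
            "detected": obs.detected,
            "n_screened": obs.n_screened,
            "assumed_sensitivity": obs.assumed_sensitivity,
            "prevalence": obs.prevalence,
            "beta1": model.beta1,
            "beta2": model.beta2,
            "t": t,
        },
    )
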