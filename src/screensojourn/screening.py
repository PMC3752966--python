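"""Prevalence and post-screen (interval-cancer) incidence under two models.

Two independence structures are supported, which differ in what the
sojourn time ``Y`` is independent of:

* **catch-up model** — ``Y`` independent of the clinical-diagnosis time
  ``X``; the joint density of surfacing cancers is ``I(x) f(y)``.
  Prevalence at the screen is the expected cumulative incidence over one
  sojourn time, ``p(t) = E[C(t + Y) - C(t)] = I(t) mu + beta2 mu^2`` for
  quadratic cumulative incidence and exponential sojourn.
* **classic model** (Markov-type) — ``Y`` independent of the onset time
  ``Z``; prevalence is onset incidence accumulated over one sojourn time,
  which for exponential sojourn reduces to ``p(t) = I(t) mu`` regardless
  of the incidence trend.

Interval-cancer incidence at ``x`` years after a screen with episode
sensitivity ``s`` is the background incidence minus the deficit of cases
removed by the screen; the deficit decays like ``exp(-x/mu)``.

Closed forms are the fast path throughout; quadrature routes evaluate the
defining integrals directly and serve as independent oracles.  Note that
the classic-model closed forms implicitly integrate the *signed* linear
onset rate over the whole past, ignoring its positivity bound; pass
``clamp_onset=True`` to the quadrature routes to study the effect of
truncating onset at that bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .incidence import QuadraticIncidenceModel
from .sojourn import ExponentialSojourn

__all__ = [
    "ScreenSetting",
    "prevalence_catchup",
    "prevalence_classic",
    "interval_incidence_catchup",
    "interval_incidence_classic",
    "expected_interval_count",
    "expected_detected",
    "interval_rate_bin_mean",
]

MODEL_KINDS = ("catchup", "classic")


@dataclass(frozen=True)
class ScreenSetting:
    """A single screening episode: time ``t`` and episode sensitivity ``s``."""

    t: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"sensitivity must lie in [0, 1], got {self.s}")


# ---------------------------------------------------------------------------
# closed-form building blocks: integrals of I and of the deficit kernel
# ---------------------------------------------------------------------------

def _int_rate(model: QuadraticIncidenceModel, a: float, b: float) -> float:
    # integral_a^b I(x) dx for the linear hazard
    u, v = a - model.t_origin, b - model.t_origin
    return model.beta1 * (v - u) + 0.5 * model.beta2 * (v * v - u * u)


def _int_exp(a: float, b: float, mu: float) -> float:
    # integral_a^b exp(-x/mu) dx
    return mu * (np.exp(-a / mu) - np.exp(-b / mu))


def _int_x_exp(a: float, b: float, mu: float) -> float:
    # integral_a^b x exp(-x/mu) dx
    return mu * ((a + mu) * np.exp(-a / mu) - (b + mu) * np.exp(-b / mu))


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------

def prevalence_catchup(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    t: float = 0.0,
    method: str = "closed",
) -> float:
    """Prevalence of the preclinical phase at time ``t``, catch-up model.

    ``E[C(t+Y) - C(t)] = I(t) mu + beta2 mu^2`` in closed form; the
    quadrature route integrates the defining expectation directly.
    """
    model._check_domain(t)
    mu = d.mu
    if method == "closed":
        return model.rate(t) * mu + model.beta2 * mu * mu
    if method == "quadrature":
        rate_t = model.rate(t)

        def integrand(y: float) -> float:
            # C_t(y) = C(t+y) - C(t) without touching x_max guards
            return d.density(y) * (rate_t * y + 0.5 * model.beta2 * y * y)

        val, _ = quad(integrand, 0.0, np.inf)
        return val
    raise ValueError(f"unknown method {method!r}")


def prevalence_classic(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    t: float = 0.0,
    method: str = "closed",
    clamp_onset: bool = False,
) -> float:
    """Prevalence at time ``t`` under the classic (Markov) model.

    Closed form ``I(t) * mu`` (exponential sojourn), valid irrespective of
    the onset positivity bound.  The quadrature route accumulates onset
    incidence surviving to ``t``; with ``clamp_onset`` the onset rate is
    floored at zero below its positivity bound, which gives a *different*
    (larger) prevalence when the bound is close to ``t``.
    """
    model._check_domain(t)
    mu = d.mu
    if method == "closed":
        return model.rate(t) * mu
    if method == "quadrature":
        lo = model.onset_positivity_bound(mu) if clamp_onset else t - 60.0 * mu

        def integrand(z: float) -> float:
            rate = model.beta1 + model.beta2 * (z - model.t_origin + mu)
            if clamp_onset:
                rate = max(rate, 0.0)
            return rate * d.survival(t - z)

        val, _ = quad(integrand, lo, t, limit=200)
        return val
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# interval-cancer incidence after a screen
# ---------------------------------------------------------------------------

def interval_incidence_catchup(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    setting: ScreenSetting,
    x: float,
    method: str = "closed",
) -> float:
    """Incidence at ``x`` years after a screen, catch-up model.

    A cancer surfacing at ``t+x`` was in the preclinical phase at the
    screen iff ``Y >= x``; it was then removed with probability ``s``:
    ``I_s(t+x) = I(t+x) * (1 - s * Pr(Y >= x))``.
    """
    if x < 0.0:
        raise ValueError(f"time since screen must be nonnegative, got {x}")
    rate = model.rate(setting.t + x)
    if method == "closed":
        return rate * (1.0 - setting.s * d.survival(x))
    if method == "quadrature":
        tail, _ = quad(d.density, x, np.inf)
        return rate * (1.0 - setting.s * tail)
    raise ValueError(f"unknown method {method!r}")


def interval_incidence_classic(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    setting: ScreenSetting,
    x: float,
    method: str = "closed",
    clamp_onset: bool = False,
) -> float:
    """Incidence at ``x`` years after a screen, classic model.

    Cancers surfacing at ``t+x`` either had onset after the screen, or had
    onset before it and escaped detection (probability ``1-s``).  With
    exponential sojourn the two convolution integrals collapse to
    ``I(t+x) - s * I(t) * exp(-x/mu)``.
    """
    if x < 0.0:
        raise ValueError(f"time since screen must be nonnegative, got {x}")
    t, s, mu = setting.t, setting.s, d.mu
    if method == "closed":
        return model.rate(t + x) - s * model.rate(t) * np.exp(-x / mu)
    if method == "quadrature":
        lo = model.onset_positivity_bound(mu) if clamp_onset else t - 60.0 * mu

        def onset(z: float) -> float:
            rate = model.beta1 + model.beta2 * (z - model.t_origin + mu)
            return max(rate, 0.0) if clamp_onset else rate

        pre, _ = quad(lambda z: onset(z) * d.density(t + x - z), lo, t, limit=200)
        post, _ = quad(lambda z: onset(z) * d.density(t + x - z), t, t + x, limit=200)
        return (1.0 - s) * pre + post
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Poisson expectations for count data
# ---------------------------------------------------------------------------

def interval_rate_bin_mean(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    setting: ScreenSetting,
    a: float,
    b: float,
    kind: str,
) -> float:
    """Mean post-screen incidence rate over the bin ``[a, b)`` since screen."""
    if not (0.0 <= a < b):
        raise ValueError(f"need 0 <= a < b, got [{a}, {b})")
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}, got {kind!r}")
    t, s, mu = setting.t, setting.s, d.mu
    base = _int_rate(model, t + a, t + b)
    if kind == "catchup":
        deficit = s * (
            model.rate(t) * _int_exp(a, b, mu) + model.beta2 * _int_x_exp(a, b, mu)
        )
    else:
        deficit = s * model.rate(t) * _int_exp(a, b, mu)
    return (base - deficit) / (b - a)


def expected_interval_count(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    setting: ScreenSetting,
    bin_: tuple[float, float],
    py: float,
    kind: str = "catchup",
) -> float:
    """Expected interval-cancer count in a bin: person-years x mean rate."""
    a, b = bin_
    if py < 0.0:
        raise ValueError(f"person-years must be nonnegative, got {py}")
    if py == 0.0:
        if not (0.0 <= a < b):
            raise ValueError(f"need 0 <= a < b, got [{a}, {b})")
        return 0.0
    return py * interval_rate_bin_mean(model, d, setting, a, b, kind)


def expected_detected(
    model: QuadraticIncidenceModel,
    d: ExponentialSojourn,
    setting: ScreenSetting,
    n_screened: float,
    kind: str = "catchup",
) -> float:
    """Expected screen-detected count: ``n * s * p(t)`` (persons, not py)."""
    if kind == "catchup":
        p = prevalence_catchup(model, d, setting.t)
    elif kind == "classic":
        p = prevalence_classic(model, d, setting.t)
    else:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}, got {kind!r}")
    return n_screened * setting.s * p
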