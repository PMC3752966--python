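"""Lead-time quantities under the two screening models.

Lead time ``L`` is the interval from screen detection to the date the
cancer would have surfaced clinically.  In the classic model with
exponential sojourn times, lead time among screen-detected cases has the
same exponential distribution as the sojourn time (memorylessness), so
mean lead time equals ``mu``.

In the catch-up model, prevalent cases at the screen over-represent long
sojourn times (length-biased sampling): being prevalent at ``t`` with
sojourn ``y`` has probability proportional to the cumulative incidence
``w(y) = C(t+y) - C(t)``, so the conditional mean sojourn is the
weighted moment ratio ``E[Y w(Y)] / E[w(Y)]``.  The time from onset to
the screen among prevalent cases keeps the unconditional sojourn
distribution (mean ``mu``), hence
``mean lead time = conditional mean sojourn - mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .incidence import QuadraticIncidenceModel
from .sojourn import ExponentialSojourn

__all__ = [
    "LeadTimeSummary",
    "conditional_mean_sojourn_catchup",
    "mean_lead_time_catchup",
    "lead_time_classic_exponential",
    "lead_time_catchup",
]


@dataclass(frozen=True)
class LeadTimeSummary:
    """Mean lead-time decomposition for screen-detected (prevalent) cases."""

    model_kind: str
    mu: float
    conditional_mean_sojourn: float
    mean_lead_time: float
    mean_time_since_onset: float

    def __post_init__(self) -> None:
        if self.conditional_mean_sojourn < self.mu - 1e-9:
            raise ValueError(
                "length-biased conditional mean sojourn cannot fall below mu"
            )
        if self.mean_lead_time < -1e-9:
            raise ValueError("mean lead time cannot be negative")


def conditional_mean_sojourn_catchup(
    model: QuadraticIncidenceModel,
    mu: float,
    t: float = 0.0,
    method: str = "closed",
) -> float:
    """Mean sojourn time among cases prevalent at ``t``, catch-up model.

    ``method="closed"`` evaluates the exponential/quadratic closed form
    ``mu * (2*beta1 + 3*beta2*mu) / (beta1 + beta2*mu)`` (for ``t`` at the
    origin; general ``t`` replaces ``beta1`` by ``I(t)``);
    ``method="moments"`` evaluates the defining weighted moment ratio
    ``(I(t) E(Y^2) + (beta2/2) E(Y^3)) / (I(t) E(Y) + (beta2/2) E(Y^2))``
    through the sojourn distribution's moments.  The two derivations are
    independent transcriptions of the same quantity.
    """
    if not (mu > 0.0):
        raise ValueError(f"mu must be positive, got {mu}")
    rate = model.rate(t)
    b2 = model.beta2
    if rate <= 0.0 and b2 <= 0.0:
        raise ValueError("prevalence is zero at this time; weight degenerate")
    if method == "closed":
        return mu * (2.0 * rate + 3.0 * b2 * mu) / (rate + b2 * mu)
    if method == "moments":
        d = ExponentialSojourn(mu=mu)
        num = rate * d.moment(2) + 0.5 * b2 * d.moment(3)
        den = rate * d.moment(1) + 0.5 * b2 * d.moment(2)
        return num / den
    raise ValueError(f"unknown method {method!r}")


def mean_lead_time_catchup(
    model: QuadraticIncidenceModel, mu: float, t: float = 0.0
) -> float:
    """Mean lead time among prevalent cases at ``t``, catch-up model.

    Conditional mean sojourn minus the mean time already spent in the
    preclinical phase (which equals ``mu``).
    """
    return conditional_mean_sojourn_catchup(model, mu, t) - mu


def lead_time_catchup(
    model: QuadraticIncidenceModel, mu: float, t: float = 0.0
) -> LeadTimeSummary:
    """Full lead-time summary for the catch-up model."""
    cond = conditional_mean_sojourn_catchup(model, mu, t)
    return LeadTimeSummary(
        model_kind="catchup",
        mu=mu,
        conditional_mean_sojourn=cond,
        mean_lead_time=cond - mu,
        mean_time_since_onset=mu,
    )


def lead_time_classic_exponential(mu: float) -> LeadTimeSummary:
    """Lead-time summary for the classic model with exponential sojourn.

    Lead time and sojourn time share the same exponential distribution,
    so mean lead time equals ``mu``; prevalent cases have conditional
    mean sojourn ``2 mu`` (time since onset plus remaining time, both
    exponential with mean ``mu``).
    """
    if not (mu > 0.0):
        raise ValueError(f"mu must be positive, got {mu}")
    return LeadTimeSummary(
        model_kind="classic",
        mu=mu,
        conditional_mean_sojourn=2.0 * mu,
        mean_lead_time=mu,
        mean_time_since_onset=mu,
    )
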