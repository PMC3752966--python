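"""Joint Poisson maximum likelihood for sojourn time and test sensitivity.

The data are a single-screen trial summary: control-arm case counts with
person-years (identifying the background incidence ``beta1 + beta2*x``),
the first-round screen-detected count among ``n_screened`` persons
(expectation ``n * s * p(t)`` with prevalence ``p`` from the chosen
model), and interval-cancer counts with person-years in yearly bins after
the screen (expectations from the model's post-screen incidence
integrated over each bin).  All counts are treated as independent Poisson
variables; the likelihood is maximized over any subset of
``(beta1, beta2, mu, s)``, with Wald intervals from the observed
information.

Two packaged fixtures reconstruct the published single-screen summaries
of the HIP mammography trial and the ERSPC-Rotterdam PSA trial from their
printed per-1000 rates; person-years are back-derived as
``cases / rate``.  The ERSPC control arm is published only in aggregate
(1067 cases at 5.26/1000 person-years over 12 years); the fixture splits
the person-years evenly over yearly bins and allocates the cases
proportionally to the published quadratic incidence at bin midpoints,
scaled to the printed total.  This reconstruction keeps ``beta1`` and
``beta2`` jointly identifiable but is an assumption: fits on the fixture
reproduce the published estimates only approximately.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from .incidence import QuadraticIncidenceModel
from .screening import MODEL_KINDS, ScreenSetting, expected_detected, interval_rate_bin_mean
from .sojourn import ExponentialSojourn

__all__ = [
    "CountBin",
    "ScreenCount",
    "TrialCountData",
    "MLEFit",
    "PARAM_NAMES",
    "negative_log_likelihood",
    "expected_counts",
    "fit_mle",
    "load_table1_fixture",
]

PARAM_NAMES = ("beta1", "beta2", "mu", "s")


@dataclass(frozen=True)
class CountBin:
    """A half-open time bin ``[start, end)`` with a case count and person-years."""

    start: float
    end: float
    cases: int
    py: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"empty bin [{self.start}, {self.end})")
        if self.cases < 0:
            raise ValueError("case counts are nonnegative")
        if not (self.py > 0.0):
            raise ValueError("person-years must be positive")

    @property
    def rate(self) -> float:
        return self.cases / self.py


@dataclass(frozen=True)
class ScreenCount:
    """First-round screen: ``detected`` cases among ``n_screened`` persons."""

    n_screened: float
    detected: int

    def __post_init__(self) -> None:
        if self.detected < 0 or self.n_screened <= 0:
            raise ValueError("invalid screen counts")

    @property
    def rate(self) -> float:
        return self.detected / self.n_screened


def _check_bins(bins: list[CountBin], what: str) -> None:
    for prev, nxt in zip(bins, bins[1:]):
        if nxt.start < prev.end:
            raise ValueError(f"{what} bins overlap at {nxt.start}")


@dataclass(frozen=True)
class TrialCountData:
    """Single-screen trial count table (control, screen, interval strata)."""

    control_bins: tuple[CountBin, ...]
    screen: ScreenCount
    interval_bins: tuple[CountBin, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_bins", tuple(self.control_bins))
        object.__setattr__(self, "interval_bins", tuple(self.interval_bins))
        _check_bins(list(self.control_bins), "control")
        _check_bins(list(self.interval_bins), "interval")

    @property
    def total_cases(self) -> int:
        return (
            sum(b.cases for b in self.control_bins)
            + self.screen.detected
            + sum(b.cases for b in self.interval_bins)
        )

    # -- tabular I/O -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("control", b.start, b.end, b.cases, b.py) for b in self.control_bins
        ]
        rows.append(("screen", None, None, self.screen.detected, self.screen.n_screened))
        rows += [
            ("interval", b.start, b.end, b.cases, b.py) for b in self.interval_bins
        ]
        return pd.DataFrame(rows, columns=["stratum", "start", "end", "cases", "py"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "TrialCountData":
        control, interval = [], []
        screen = None
        for row in frame.itertuples(index=False):
            stratum = str(row.stratum)
            if stratum == "screen":
                if screen is not None:
                    raise ValueError("multiple screen rows")
                screen = ScreenCount(n_screened=float(row.py), detected=int(row.cases))
            elif stratum in ("control", "interval"):
                b = CountBin(
                    start=float(row.start),
                    end=float(row.end),
                    cases=int(row.cases),
                    py=float(row.py),
                )
                (control if stratum == "control" else interval).append(b)
            else:
                raise ValueError(f"unknown stratum {stratum!r}")
        if screen is None:
            raise ValueError("missing screen row")
        return cls(
            control_bins=tuple(control),
            screen=screen,
            interval_bins=tuple(interval),
            label=label,
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "TrialCountData":
        return cls.from_frame(pd.read_csv(path), label=label)

    def scaled(self, factor: float) -> "TrialCountData":
        """Rescale all person-years, persons and counts by ``factor``."""
        scale_bin = lambda b: CountBin(
            b.start, b.end, int(round(b.cases * factor)), b.py * factor
        )
        return TrialCountData(
            control_bins=tuple(scale_bin(b) for b in self.control_bins),
            screen=ScreenCount(
                self.screen.n_screened * factor,
                int(round(self.screen.detected * factor)),
            ),
            interval_bins=tuple(scale_bin(b) for b in self.interval_bins),
            label=self.label,
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _unpack(params) -> tuple[float, float, float, float]:
    if isinstance(params, dict):
        missing = [k for k in PARAM_NAMES if k not in params]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return tuple(float(params[k]) for k in PARAM_NAMES)
    b1, b2, mu, s = params
    return float(b1), float(b2), float(mu), float(s)


def expected_counts(
    data: TrialCountData, params, model_kind: str
) -> tuple[np.ndarray, float, np.ndarray]:
    """Poisson expectations for every count in the table.

    Returns (control expectations, screen expectation, interval
    expectations) under the given ``(beta1, beta2, mu, s)``.
    """
    beta1, beta2, mu, s = _unpack(params)
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    model = QuadraticIncidenceModel(beta1=beta1, beta2=beta2)
    d = ExponentialSojourn(mu=mu)
    setting = ScreenSetting(t=0.0, s=s)
    control = np.array(
        [
            b.py
            * (beta1 + 0.5 * beta2 * (b.start + b.end))  # mean rate over the bin
            for b in data.control_bins
        ]
    )
    screen = expected_detected(model, d, setting, data.screen.n_screened, model_kind)
    interval = np.array(
        [
            b.py * interval_rate_bin_mean(model, d, setting, b.start, b.end, model_kind)
            for b in data.interval_bins
        ]
    )
    return control, screen, interval


def _observed(data: TrialCountData) -> np.ndarray:
    return np.array(
        [b.cases for b in data.control_bins]
        + [data.screen.detected]
        + [b.cases for b in data.interval_bins],
        dtype=float,
    )


def negative_log_likelihood(
    data: TrialCountData,
    params,
    model_kind: str,
    include_constants: bool = False,
) -> float:
    """Poisson negative log-likelihood of the count table.

    One term per control bin, one for the screen-detected count, one per
    interval bin.  By default the ``log k!`` constants are dropped — they
    are identical for both model kinds on the same data, so likelihood
    differences between kinds remain valid.  Out-of-bounds parameters
    (``mu <= 0``, ``s`` outside ``[0, 1]``, a nonpositive expectation)
    return ``+inf``.
    """
    beta1, beta2, mu, s = _unpack(params)
    if not (mu > 0.0) or not (0.0 <= s <= 1.0) or beta1 < 0.0:
        return math.inf
    try:
        control, screen, interval = expected_counts(
            data, (beta1, beta2, mu, s), model_kind
        )
    except ValueError:
        return math.inf
    e = np.concatenate([control, [screen], interval])
    k = _observed(data)
    if np.any(e <= 0.0) or not np.all(np.isfinite(e)):
        return math.inf
    nll = float(np.sum(e - k * np.log(e)))
    if include_constants:
        nll += float(np.sum(gammaln(k + 1.0)))
    return nll


@dataclass(frozen=True)
class MLEFit:
    """Result of :func:`fit_mle`.

    ``estimates`` holds all four parameters (fitted or fixed); ``cov`` is
    the inverse observed information over the free parameters in
    ``free_names`` order; ``ci`` are symmetric Wald intervals.  ``loglik``
    includes the Poisson constants, so values are comparable across model
    kinds on the same data.
    """

    model_kind: str
    estimates: dict
    fixed: dict
    free_names: tuple[str, ...]
    loglik: float
    cov: np.ndarray
    se: dict
    ci: dict
    level: float
    converged: bool
    s_at_boundary: bool
    label: str = ""

    @property
    def mu(self) -> float:
        return self.estimates["mu"]

    @property
    def s(self) -> float:
        return self.estimates["s"]


_TRANSFORMS = {
    # optimizer works on log(beta1), log(beta2), log(mu); s stays natural
    "beta1": (math.log, math.exp, (-25.0, 0.0)),
    "beta2": (math.log, math.exp, (-30.0, 0.0)),
    "mu": (math.log, math.exp, (math.log(1e-3), math.log(1e3))),
    "s": (lambda v: v, lambda v: v, (1e-9, 1.0)),
}


def _default_start(data: TrialCountData, fixed: dict) -> dict:
    mids = np.array([(b.start + b.end) / 2.0 for b in data.control_bins])
    rates = np.array([b.rate for b in data.control_bins])
    pys = np.array([b.py for b in data.control_bins])
    if "beta2" in fixed:
        beta2 = fixed["beta2"]
        beta1 = max(float(np.average(rates, weights=pys)) - beta2 * float(
            np.average(mids, weights=pys)
        ), 1e-8)
    elif len(data.control_bins) >= 2:
        beta2, beta1 = np.polyfit(mids, rates, 1, w=np.sqrt(pys))
        beta1 = max(float(beta1), 1e-8)
        beta2 = max(float(beta2), 1e-10)
    else:
        beta1 = max(float(rates[0]), 1e-8)
        beta2 = 1e-10
    s0 = fixed.get("s", 0.9)
    p0 = data.screen.rate / s0
    mu0 = max(p0 / beta1, 0.05)
    return {"beta1": beta1, "beta2": beta2, "mu": mu0, "s": s0}


def fit_mle(
    data: TrialCountData,
    model_kind: str,
    fixed: dict | None = None,
    start: dict | None = None,
    level: float = 0.95,
    mu_start_factors: tuple[float, ...] = (0.3, 1.0, 3.0),
) -> MLEFit:
    """Maximize the Poisson likelihood over the free parameters.

    ``fixed`` maps parameter names to values held constant (e.g. the
    background trend for the HIP fixture).  The optimizer is L-BFGS-B on
    a partially transformed scale (log for the positive parameters, a
    ``[0, 1]`` box for ``s``), restarted deterministically from a small
    grid of sojourn-time starting values derived from the direct
    prevalence/incidence ratio.  A sensitivity estimate on the upper
    boundary is flagged, not treated as an error.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown fixed parameter {name!r}")
    free = tuple(n for n in PARAM_NAMES if n not in fixed)
    if "mu" not in free or "s" not in free:
        raise ValueError("mu and s must be free parameters")

    base = _default_start(data, fixed)
    if start:
        base.update(start)
    base.update(fixed)

    def to_vec(values: dict) -> np.ndarray:
        return np.array([_TRANSFORMS[n][0](values[n]) for n in free])

    def from_vec(vec: np.ndarray) -> dict:
        values = dict(fixed)
        for name, v in zip(free, vec):
            values[name] = float(_TRANSFORMS[name][1](v))
        return values

    def objective(vec: np.ndarray) -> float:
        return negative_log_likelihood(data, from_vec(vec), model_kind)

    bounds = [_TRANSFORMS[n][2] for n in free]
    results = []
    for factor in mu_start_factors:
        trial = dict(base)
        trial["mu"] = min(max(base["mu"] * factor, 2e-3), 5e2)
        res = minimize(
            objective,
            to_vec(trial),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
        )
        results.append(res)
    ok = [r for r in results if r.success and np.isfinite(r.fun)]
    if not ok:
        raise RuntimeError(
            "likelihood optimization did not converge from any start: "
            + "; ".join(str(r.message) for r in results)
        )
    best = min(ok, key=lambda r: r.fun)
    estimates = from_vec(best.x)
    s_at_boundary = "s" in free and estimates["s"] >= 1.0 - 1e-7

    # observed information on the natural scale
    hess_names = tuple(n for n in free if not (n == "s" and s_at_boundary))

    def nll_natural(vec: np.ndarray) -> float:
        values = dict(estimates)
        for name, v in zip(hess_names, vec):
            values[name] = v
        return negative_log_likelihood(data, values, model_kind)

    x0 = np.array([estimates[n] for n in hess_names])
    hess = approx_hess(x0, nll_natural)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((len(hess_names), len(hess_names)), np.nan)
    z = float(norm.ppf(0.5 + level / 2.0))
    se, ci = {}, {}
    for i, name in enumerate(hess_names):
        var = cov[i, i]
        sd = math.sqrt(var) if var > 0 else math.nan
        se[name] = sd
        ci[name] = (estimates[name] - z * sd, estimates[name] + z * sd)
    return MLEFit(
        model_kind=model_kind,
        estimates=estimates,
        fixed=fixed,
        free_names=hess_names,
        loglik=-negative_log_likelihood(
            data, estimates, model_kind, include_constants=True
        ),
        cov=cov,
        se=se,
        ci=ci,
        level=level,
        converged=True,
        s_at_boundary=s_at_boundary,
        label=data.label,
    )


# ---------------------------------------------------------------------------
# packaged trial fixtures
# ---------------------------------------------------------------------------

#: published per-1000 rates backing the fixtures (control and interval rates
#: per 1000 person-years; detection per 1000 persons)
PRINTED_RATES_PER_1000 = {
    "hip": {
        "control": 1.87,
        "detection": 2.73,
        "interval": (0.61, 1.03, 0.31, 1.16, 2.25),
    },
    "erspc": {
        "control": 5.26,
        "detection": 54.0,
        "interval": (0.90, 0.54, 1.31, 1.34),
    },
}

#: background trend fixed in the published HIP fits (per person-year per year)
HIP_FIXED_BETA2 = 0.021e-3


def load_table1_fixture(trial: str) -> TrialCountData:
    """Load a packaged single-screen trial fixture (``"hip"`` or ``"erspc"``)."""
    key = trial.strip().lower()
    if key not in ("hip", "erspc"):
        raise ValueError(f"unknown trial {trial!r}; expected 'hip' or 'erspc'")
    text = resources.files("screensojourn.data").joinpath(f"{key}.csv").read_text()
    return TrialCountData.from_frame(pd.read_csv(io.StringIO(text)), label=key)
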