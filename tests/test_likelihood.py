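import math

import numpy as np
import pytest

from screensojourn import (
    CountBin,
    ScreenCount,
    SimConfig,
    TrialCountData,
    expected_counts,
    fit_mle,
    load_table1_fixture,
    negative_log_likelihood,
    simulate_trial,
)
from screensojourn.likelihood import HIP_FIXED_BETA2, PRINTED_RATES_PER_1000


@pytest.fixture(scope="module")
def erspc():
    return load_table1_fixture("erspc")


@pytest.fixture(scope="module")
def hip():
    return load_table1_fixture("hip")


class TestFixtures:
    def test_unknown_trial_rejected(self):
        with pytest.raises(ValueError):
            load_table1_fixture("nlst")

    def test_erspc_totals(self, erspc):
        assert sum(b.cases for b in erspc.control_bins) == 1067
        assert erspc.screen.detected == 1078
        assert [b.cases for b in erspc.interval_bins] == [17, 10, 24, 24]

    def test_hip_counts(self, hip):
        assert hip.control_bins[0].cases == 285
        assert hip.screen.detected == 55
        assert [b.cases for b in hip.interval_bins] == [13, 7, 1, 3, 5]

    @pytest.mark.parametrize("trial", ["hip", "erspc"])
    def test_rates_reproduce_printed_values(self, trial):
        """Back-derived person-years must return the published per-1000
        rates at their printed precision."""
        data = load_table1_fixture(trial)
        printed = PRINTED_RATES_PER_1000[trial]
        control_rate = (
            1000
            * sum(b.cases for b in data.control_bins)
            / sum(b.py for b in data.control_bins)
        )
        assert control_rate == pytest.approx(printed["control"], abs=0.005)
        assert 1000 * data.screen.rate == pytest.approx(printed["detection"], abs=0.005)
        for b, rate in zip(data.interval_bins, printed["interval"]):
            assert 1000 * b.rate == pytest.approx(rate, abs=0.005)

    def test_screened_persons_back_derived(self, erspc, hip):
        assert erspc.screen.n_screened == pytest.approx(1078 / 0.054, rel=1e-9)
        assert hip.screen.n_screened == pytest.approx(55 / 0.00273, rel=1e-9)

    def test_csv_round_trip(self, erspc, tmp_path):
        path = tmp_path / "erspc.csv"
        erspc.to_csv(path)
        again = TrialCountData.from_csv(path, label=erspc.label)
        assert again.screen == erspc.screen
        assert again.control_bins == erspc.control_bins
        assert again.interval_bins == erspc.interval_bins

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrialCountData(
                control_bins=(
                    CountBin(0, 2, 5, 100.0),
                    CountBin(1, 3, 5, 100.0),
                ),
                screen=ScreenCount(1000, 10),
                interval_bins=(),
            )


class TestNegativeLogLikelihood:
    TINY = TrialCountData(
        control_bins=(CountBin(0, 1, 7, 1000.0),),
        screen=ScreenCount(5000, 40),
        interval_bins=(CountBin(0, 1, 3, 4000.0),),
    )

    def test_matches_manual_poisson_terms(self):
        params = {"beta1": 0.006, "beta2": 1e-4, "mu": 4.0, "s": 0.8}
        control, screen, interval = expected_counts(self.TINY, params, "catchup")
        manual = 0.0
        for e, k in zip(
            np.concatenate([control, [screen], interval]), [7.0, 40.0, 3.0]
        ):
            manual += e - k * math.log(e)
        assert negative_log_likelihood(self.TINY, params, "catchup") == pytest.approx(
            manual, rel=1e-12
        )

    def test_saturated_expectations_minimize_each_term(self):
        # e - k log e is minimized at e = k for each Poisson term
        k = 40.0
        term = lambda e: e - k * math.log(e)
        assert term(k) < term(k * 1.05)
        e_screen = expected_counts(
            self.TINY, {"beta1": 0.007, "beta2": 0.0, "mu": 2.0, "s": 0.8}, "catchup"
        )[1]
        assert term(k) <= term(e_screen)

    @pytest.mark.parametrize(
        "bad",
        [
            {"beta1": 0.006, "beta2": 1e-4, "mu": -1.0, "s": 0.8},
            {"beta1": 0.006, "beta2": 1e-4, "mu": 4.0, "s": 1.2},
            {"beta1": -0.1, "beta2": 1e-4, "mu": 4.0, "s": 0.8},
        ],
    )
    def test_out_of_bounds_parameters_return_infinity(self, bad):
        val = negative_log_likelihood(self.TINY, bad, "classic")
        assert math.isinf(val) and val > 0

    def test_constants_shift_is_model_independent(self, erspc):
        params = {"beta1": 0.0033, "beta2": 3e-4, "mu": 10.0, "s": 0.9}
        for kind in ("catchup", "classic"):
            with_c = negative_log_likelihood(erspc, params, kind, include_constants=True)
            without = negative_log_likelihood(erspc, params, kind)
            shift = with_c - without
            assert shift == pytest.approx(
                sum(math.lgamma(k + 1) for k in [b.cases for b in erspc.control_bins]
                    + [erspc.screen.detected]
                    + [b.cases for b in erspc.interval_bins]),
                rel=1e-12,
            )


class TestFits:
    def test_erspc_catchup_fits_better_than_classic(self, erspc):
        f_catch = fit_mle(erspc, "catchup")
        f_classic = fit_mle(erspc, "classic")
        assert f_catch.loglik > f_classic.loglik
        assert f_catch.estimates["mu"] < f_classic.estimates["mu"]
        assert 0.0 < f_catch.estimates["s"] <= 1.0

    def test_hip_models_nearly_agree(self, hip):
        """With a short sojourn time the two independence structures are
        practically indistinguishable."""
        fixed = {"beta2": HIP_FIXED_BETA2}
        f_catch = fit_mle(hip, "catchup", fixed=fixed)
        f_classic = fit_mle(hip, "classic", fixed=fixed)
        assert abs(f_catch.estimates["mu"] - f_classic.estimates["mu"]) < 0.1
        assert abs(f_catch.loglik - f_classic.loglik) < 0.5

    def test_no_trend_makes_fits_identical(self, hip):
        fixed = {"beta2": 0.0}
        f_catch = fit_mle(hip, "catchup", fixed=fixed)
        f_classic = fit_mle(hip, "classic", fixed=fixed)
        # identical models; allow for optimizer stopping resolution
        assert f_catch.estimates["mu"] == pytest.approx(
            f_classic.estimates["mu"], rel=1e-4
        )
        assert f_catch.loglik == pytest.approx(f_classic.loglik, abs=1e-6)

    def test_fit_is_deterministic(self, erspc):
        a = fit_mle(erspc, "catchup")
        b = fit_mle(erspc, "catchup")
        assert a.estimates == b.estimates

    def test_rescaling_counts_and_person_time_leaves_mu_s(self, erspc):
        f1 = fit_mle(erspc, "catchup")
        f2 = fit_mle(erspc.scaled(2.0), "catchup")
        assert f2.estimates["mu"] == pytest.approx(f1.estimates["mu"], rel=1e-4)
        assert f2.estimates["s"] == pytest.approx(f1.estimates["s"], rel=1e-4)

    def test_wald_interval_brackets_estimate(self, erspc):
        f = fit_mle(erspc, "catchup")
        lo, hi = f.ci["mu"]
        assert lo < f.estimates["mu"] < hi
        assert f.se["mu"] > 0
        cov = f.cov
        assert np.allclose(cov, cov.T)

    def test_mu_and_s_must_stay_free(self, erspc):
        with pytest.raises(ValueError):
            fit_mle(erspc, "catchup", fixed={"mu": 5.0})
        with pytest.raises(ValueError):
            fit_mle(erspc, "catchup", fixed={"gamma": 1.0})


class TestParameterRecovery:
    """Simulated-cohort oracle: the fit must recover known parameters."""

    CONTROL_BINS = [(i, i + 1) for i in range(12)]
    INTERVAL_BINS = [(i, i + 1) for i in range(4)]

    def _run(self, kind, truth, n_rep, n_subjects, follow_up):
        hits, errs, zs = 0, [], []
        for rep in range(n_rep):
            cfg = SimConfig(
                model_kind=kind,
                beta1=truth["beta1"],
                beta2=truth["beta2"],
                mu=truth["mu"],
                s=truth["s"],
                n_subjects=n_subjects,
                follow_up=follow_up,
                seed=5000 + rep,
            )
            _, _, counts = simulate_trial(cfg, self.CONTROL_BINS, self.INTERVAL_BINS)
            fit = fit_mle(counts, kind, mu_start_factors=(1.0,))
            lo, hi = fit.ci["mu"]
            hits += lo <= truth["mu"] <= hi
            errs.append(fit.estimates["mu"] - truth["mu"])
        return hits / n_rep, np.asarray(errs)

    def test_catchup_recovery_bias_and_coverage(self):
        truth = {"beta1": 0.0034342704, "beta2": 2 * 0.0001796227, "mu": 9.36, "s": 0.87}
        coverage, errs = self._run("catchup", truth, 200, 20_000, 100.0)
        assert 0.90 <= coverage <= 0.98
        assert abs(errs.mean()) < 3.0 * errs.std() / math.sqrt(len(errs))

    def test_classic_recovery_bias_and_coverage(self):
        # parameters with the onset positivity bound far before the screen,
        # where the truncated onset process matches the closed forms
        truth = {"beta1": 0.005, "beta2": 1e-4, "mu": 3.0, "s": 0.85}
        coverage, errs = self._run("classic", truth, 200, 20_000, 12.0)
        assert 0.90 <= coverage <= 0.98
        assert abs(errs.mean()) < 3.0 * errs.std() / math.sqrt(len(errs))
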