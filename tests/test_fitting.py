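"""Likelihood, multi-start MLE, extension/transfer fits, recovery harness."""

import dataclasses
import math

import numpy as np
import pytest

import ownsync as osy
from ownsync.fitting import DEFAULT_BOUNDS
from ownsync.observer_models import ObserverParams
from ownsync.synthetic_data import ConditionCounts

SIGMAS = {0: 116.0, 30: 141.0, 50: 178.0}


def bernoulli_expansion_oracle(counts, params):
    """Trial-by-trial Bernoulli log-loss on expanded data."""
    total = 0.0
    for c in counts:
        p = osy.p_report_common(c.asynchrony, params, c.noise)
        for _ in range(c.n_yes):
            total -= math.log(p)
        for _ in range(c.n_trials - c.n_yes):
            total -= math.log(1 - p)
    return total


class TestNegLogLikelihood:
    def test_pure_lapse_is_n_log_two(self, typical_counts):
        lapser = ObserverParams(model="BCI", p_same=0.8, sigma_by_noise=SIGMAS, lapse=1.0)
        n_total = sum(c.n_trials for c in typical_counts)
        assert osy.neg_log_likelihood(typical_counts, lapser) == pytest.approx(
            n_total * math.log(2), rel=1e-12
        )

    def test_single_saturated_cell(self):
        # huge criterion puts all mass inside: p = 1 - lapse/2 = 0.95
        params = ObserverParams(model="FC", k0=1e6, sigma_by_noise={0: 116.0}, lapse=0.1)
        cell = [ConditionCounts("P01", "ownership", 0, 0, 12, 12)]
        assert osy.neg_log_likelihood(cell, params) == pytest.approx(
            -12 * math.log(0.95), rel=1e-9
        )

    def test_matches_trialwise_expansion(self, typical_counts, typical_bci_params):
        nll = osy.neg_log_likelihood(typical_counts, typical_bci_params)
        assert nll == pytest.approx(
            bernoulli_expansion_oracle(typical_counts, typical_bci_params), rel=1e-9
        )

    def test_invariant_to_row_order_and_cell_splitting(self, typical_counts, typical_bci_params):
        nll = osy.neg_log_likelihood(typical_counts, typical_bci_params)
        reversed_nll = osy.neg_log_likelihood(typical_counts[::-1], typical_bci_params)
        assert reversed_nll == pytest.approx(nll, rel=1e-12)
        split = []
        for c in typical_counts:
            a = c.n_yes // 2
            split.append(dataclasses.replace(c, n_trials=6, n_yes=a))
            split.append(dataclasses.replace(c, n_trials=6, n_yes=c.n_yes - a))
        assert osy.neg_log_likelihood(split, typical_bci_params) == pytest.approx(
            nll, rel=1e-12
        )

    def test_scale_invariance(self, typical_counts):
        params = ObserverParams(model="BCI", p_same=0.8, sigma_by_noise=SIGMAS, lapse=0.08)
        c = 2.5
        scaled_counts = [
            dataclasses.replace(r, asynchrony=int(r.asynchrony * c)) for r in typical_counts
        ]
        scaled_params = ObserverParams(
            model="BCI", p_same=0.8,
            sigma_by_noise={k: v * c for k, v in SIGMAS.items()},
            sigma_s=348.0 * c, lapse=0.08,
        )
        assert osy.neg_log_likelihood(scaled_counts, scaled_params) == pytest.approx(
            osy.neg_log_likelihood(typical_counts, params), rel=1e-10
        )

    def test_mixed_tasks_rejected(self, typical_counts, typical_bci_params):
        other = dataclasses.replace(typical_counts[0], task="synchrony")
        with pytest.raises(ValueError):
            osy.neg_log_likelihood(list(typical_counts) + [other], typical_bci_params)


class TestFitSingle:
    def test_deterministic_given_seed(self, typical_counts):
        a = osy.fit_single(typical_counts, "BCI", n_starts=8, seed=42)
        b = osy.fit_single(typical_counts, "BCI", n_starts=8, seed=42)
        assert a.log_likelihood == b.log_likelihood
        assert a.params == b.params
        assert a.best_start_index == b.best_start_index

    def test_information_criteria_consistency(self, typical_counts):
        fit = osy.fit_single(typical_counts, "BCI", n_starts=8, seed=1)
        assert fit.n_par == 5
        assert fit.n_trials == 252
        assert fit.aic == pytest.approx(2 * 5 - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(5 * math.log(252) - 2 * fit.log_likelihood)
        assert fit.log_likelihood <= 0

    def test_free_parameter_counts_by_model(self, typical_counts):
        assert osy.fit_single(typical_counts, "FC", n_starts=6, seed=1).n_par == 5
        assert osy.fit_single(typical_counts, "BCI_STAR", n_starts=6, seed=1).n_par == 6

    def test_nested_model_never_fits_better(self, typical_counts):
        bci = osy.fit_single(typical_counts, "BCI", n_starts=20, seed=3)
        star = osy.fit_single(typical_counts, "BCI_STAR", n_starts=30, seed=4)
        assert star.log_likelihood >= bci.log_likelihood - 1e-3

    def test_estimates_approach_truth_at_large_n(self, ownership_design):
        truth = ObserverParams(model="BCI", p_same=0.8, sigma_by_noise=SIGMAS, lapse=0.05)
        big = dataclasses.replace(ownership_design, reps_per_cell=1200)
        counts = osy.simulate_responses(big, truth, "big", seed=1)
        fit = osy.fit_single(counts, "BCI", n_starts=20, seed=2)
        est = fit.params
        assert est.p_same == pytest.approx(0.8, rel=0.05)
        for lvl, sig in SIGMAS.items():
            assert est.sigma_by_noise[lvl] == pytest.approx(sig, rel=0.05)
        # lapse precision is bounded by binomial noise in the tail cells
        assert est.lapse == pytest.approx(0.05, abs=0.01)

    def test_error_shrinks_with_repetitions(self, ownership_design):
        truth = ObserverParams(model="BCI", p_same=0.75, sigma_by_noise=SIGMAS, lapse=0.06)
        errs = {}
        for reps in (12, 1200):
            design = dataclasses.replace(ownership_design, reps_per_cell=reps)
            err = []
            for i in range(4):
                counts = osy.simulate_responses(design, truth, f"c{i}", seed=20 + i)
                fit = osy.fit_single(counts, "BCI", n_starts=10, seed=30 + i)
                err.append(abs(fit.params.p_same - 0.75))
            errs[reps] = np.median(err)
        assert errs[1200] < errs[12]

    def test_single_noise_level_fc_matches_bci(self):
        design = osy.StimulusDesign(
            task="ownership", asynchronies=(-500, -300, -150, 0, 150, 300, 500),
            noise_levels=(0,),
        )
        truth = ObserverParams(model="BCI", p_same=0.8, sigma_by_noise={0: 116.0}, lapse=0.05)
        counts = osy.simulate_responses(design, truth, "sn", seed=9)
        bci = osy.fit_single(counts, "BCI", n_starts=20, seed=1)
        fc = osy.fit_single(counts, "FC", n_starts=20, seed=2)
        # with one noise level the fixed criterion spans the same curve family
        assert fc.log_likelihood >= bci.log_likelihood - 1e-3


class TestFitExtension:
    @pytest.fixture(scope="class")
    def two_task_counts(self, ownership_design, synchrony_design):
        own = ObserverParams(model="BCI", p_same=0.85, sigma_by_noise=SIGMAS, lapse=0.06)
        syn = ObserverParams(model="BCI", p_same=0.60, sigma_by_noise=SIGMAS, lapse=0.06)
        co = osy.simulate_responses(ownership_design, own, "P01", seed=13)
        cs = osy.simulate_responses(synchrony_design, syn, "P01", seed=13)
        return co, cs

    def test_parameter_sharing_and_counts(self, two_task_counts):
        co, cs = two_task_counts
        shared = osy.fit_extension(co, cs, shared_p_same=True, n_starts=10, seed=1)
        separate = osy.fit_extension(co, cs, shared_p_same=False, n_starts=10, seed=1)
        assert shared.n_par == 5 and separate.n_par == 6
        assert shared.n_trials == separate.n_trials == 504
        po, ps = shared.params["ownership"], shared.params["synchrony"]
        assert po.p_same == ps.p_same
        assert po.sigma_by_noise == ps.sigma_by_noise and po.lapse == ps.lapse
        so, ss = separate.params["ownership"], separate.params["synchrony"]
        assert so.sigma_by_noise == ss.sigma_by_noise and so.lapse == ss.lapse
        assert so.p_same != ss.p_same

    def test_separate_prior_nests_shared(self, two_task_counts):
        co, cs = two_task_counts
        shared = osy.fit_extension(co, cs, shared_p_same=True, n_starts=10, seed=2)
        separate = osy.fit_extension(co, cs, shared_p_same=False, n_starts=10, seed=2)
        assert separate.log_likelihood >= shared.log_likelihood - 1e-3

    def test_separate_fit_recovers_task_priors(self, two_task_counts):
        co, cs = two_task_counts
        separate = osy.fit_extension(co, cs, shared_p_same=False, n_starts=15, seed=3)
        assert separate.params["ownership"].p_same > separate.params["synchrony"].p_same


class TestTransfer:
    @pytest.fixture(scope="class")
    def source_and_target(self, ownership_design, synchrony_design):
        own = ObserverParams(model="BCI", p_same=0.85, sigma_by_noise=SIGMAS, lapse=0.06)
        syn = ObserverParams(model="BCI", p_same=0.60, sigma_by_noise=SIGMAS, lapse=0.06)
        co = osy.simulate_responses(ownership_design, own, "P01", seed=17)
        cs = osy.simulate_responses(synchrony_design, syn, "P01", seed=17)
        source = osy.fit_single(co, "BCI", n_starts=12, seed=5)
        return source, cs

    def test_full_transfer_is_plain_evaluation(self, source_and_target):
        source, target = source_and_target
        full = osy.transfer_evaluate(source, target, mode="full")
        assert full.n_par == 0
        assert full.log_likelihood == pytest.approx(
            -osy.neg_log_likelihood(target, source.params), rel=1e-12
        )
        assert full.aic == pytest.approx(-2 * full.log_likelihood)

    def test_partial_transfer_nests_full(self, source_and_target):
        source, target = source_and_target
        full = osy.transfer_evaluate(source, target, mode="full")
        partial = osy.transfer_evaluate(source, target, mode="partial", n_starts=8, seed=1)
        assert partial.n_par == 1
        assert partial.log_likelihood >= full.log_likelihood - 1e-9
        # only the prior moved; sensory and lapse parameters carried over
        assert partial.params.sigma_by_noise == source.params.sigma_by_noise
        assert partial.params.lapse == source.params.lapse

    def test_partial_beats_full_when_priors_differ(self, source_and_target):
        source, target = source_and_target
        full = osy.transfer_evaluate(source, target, mode="full")
        partial = osy.transfer_evaluate(source, target, mode="partial", n_starts=8, seed=2)
        assert partial.aic < full.aic

    def test_mode_validation(self, source_and_target):
        source, target = source_and_target
        with pytest.raises(ValueError):
            osy.transfer_evaluate(source, target, mode="sideways")


class TestParameterRecovery:
    def test_report_structure_and_finite_errors(self, ownership_design):
        report = osy.run_parameter_recovery(
            "BCI", 4, ownership_design, n_starts=8, seed=21
        )
        assert report.n_observers == 4
        assert set(report.summary.parameter) == {
            "p_same", "sigma_0", "sigma_30", "sigma_50", "lapse",
        }
        for name in ("p_same", "lapse"):
            assert np.isfinite(report.table[f"abs_err_{name}"]).all()
            lo, hi = DEFAULT_BOUNDS[name]
            assert report.table[f"est_{name}"].between(lo, hi).all()

    def test_fc_recovery_tabulates_criterion(self, ownership_design):
        report = osy.run_parameter_recovery(
            "FC", 3, ownership_design, n_starts=8, seed=22
        )
        assert "true_k0" in report.table.columns
        assert "est_k0" in report.table.columns
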