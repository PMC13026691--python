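import math

import numpy as np
import pytest
from scipy.stats import norm

import vitaltraj as vt
from vitaltraj.gbtm_core import (
    FitError,
    GbtmModel,
    GbtmSpec,
    average_posterior_probability,
    bic,
    build_design,
    e_step,
    fit,
    group_mean,
    m_step,
    model_from_dict,
    model_to_dict,
    patient_loglik,
    permute_groups,
)
from vitaltraj.preprocess import PatientSeries

from .conftest import make_series


def make_model(coefs, sigmas, mixing, orders=None, variance_mode="group"):
    """Assemble a GbtmModel from plain nested dicts/lists."""
    G = len(mixing)
    channels = list(coefs)
    if orders is None:
        orders = {ch: len(coefs[ch][0]) - 1 for ch in channels}
    spec = GbtmSpec(n_groups=G, orders=orders, variance_mode=variance_mode)
    return GbtmModel(
        spec=spec,
        mixing=np.asarray(mixing, float),
        coefs={ch: np.asarray(v, float) for ch, v in coefs.items()},
        sigmas={ch: np.asarray(v, float) for ch, v in sigmas.items()},
    )


def naive_patient_loglik(model, series):
    """Direct-summation oracle: per-observation normal log-densities summed
    one by one, mixture combined by a plain (unshifted) sum."""
    comp = []
    for g in range(model.n_groups):
        ll = 0.0
        for ch, (times, values) in series.observed.items():
            beta = model.coefs[ch][g]
            sigma = model.sigmas[ch][g]
            for t, x in zip(times, values):
                mu = sum(b * t ** k for k, b in enumerate(beta))
                ll += float(norm.logpdf(x, mu, sigma))
        comp.append(ll)
    total = math.log(sum(p * math.exp(c) for p, c in zip(model.mixing, comp)))
    return np.array(comp), total


class TestGroupMean:
    def test_constant(self):
        assert group_mean(np.array([36.8, 0.0, 0.0]), 12.0) == pytest.approx(36.8)

    def test_quadratic_by_hand(self):
        assert group_mean(np.array([1.0, 1.0, 1.0]), 2.0) == pytest.approx(7.0)

    def test_linear(self):
        assert group_mean(np.array([0.0, 2.0]), 3.0) == pytest.approx(6.0)


class TestPatientLoglik:
    def test_single_group_total_equals_component(self):
        model = make_model({"TEMP": [[0.0, 0.0]]}, {"TEMP": [1.0]}, [1.0])
        s = PatientSeries("p", {"TEMP": (np.array([2.0, 9.0]), np.array([0.3, -0.2]))})
        comp, total = patient_loglik(model, s)
        assert total == pytest.approx(comp[0])

    def test_standard_normal_peak(self):
        # one observation exactly at the mean, sigma 1 -> -0.5*log(2*pi)
        model = make_model({"HR": [[1.5, 0.0]]}, {"HR": [1.0]}, [1.0])
        s = PatientSeries("p", {"HR": (np.array([6.0]), np.array([1.5]))})
        _, total = patient_loglik(model, s)
        assert total == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def small_coefs():
            return np.column_stack([rng.normal(size=3), 0.05 * rng.normal(size=3)])

        model = make_model(
            {"TEMP": small_coefs(), "HR": small_coefs()},
            {"TEMP": rng.uniform(0.5, 2, 3), "HR": rng.uniform(0.5, 2, 3)},
            rng.dirichlet(np.ones(3)),
        )
        for s in make_series(rng, n_patients=4):
            comp, total = patient_loglik(model, s)
            comp_naive, total_naive = naive_patient_loglik(model, s)
            assert comp == pytest.approx(comp_naive, abs=1e-10)
            assert total == pytest.approx(total_naive, abs=1e-10)

    def test_log_sum_exp_stability(self):
        # components ~600 orders of magnitude apart must not underflow
        model = make_model(
            {"HR": [[0.0, 0.0], [60.0, 0.0]]}, {"HR": [1.0, 1.0]}, [0.5, 0.5]
        )
        s = PatientSeries("p", {"HR": (np.array([0.0]), np.array([0.0]))})
        comp, total = patient_loglik(model, s)
        assert comp[0] - comp[1] > 1300  # e^1300 ~ 10^565
        assert np.isfinite(total)
        assert total == pytest.approx(math.log(0.5) + comp[0], abs=1e-10)

    def test_unobserved_channels_contribute_nothing(self):
        model = make_model(
            {"TEMP": [[0.0, 0.0]], "HR": [[0.0, 0.0]]},
            {"TEMP": [1.0], "HR": [1.0]}, [1.0],
        )
        s = PatientSeries("p", {"TEMP": (np.array([3.0]), np.array([0.7]))})
        _, total = patient_loglik(model, s)
        expected = math.log(norm.pdf(0.7, 0.0, 1.0))
        assert total == pytest.approx(expected, abs=1e-12)


class TestEStep:
    def test_identical_groups_give_uniform_posterior(self):
        rng = np.random.default_rng(0)
        model = make_model(
            {"HR": [[0.1, 0.0], [0.1, 0.0]]}, {"HR": [1.0, 1.0]}, [0.5, 0.5]
        )
        for a in e_step(model, make_series(rng, n_patients=5, channels=("HR",))):
            assert a.posterior == pytest.approx([0.5, 0.5], abs=1e-12)
            assert a.max_posterior == pytest.approx(0.5)

    def test_separated_groups_dominance(self):
        model = make_model(
            {"HR": [[0.0, 0.0], [20.0, 0.0]]}, {"HR": [1.0, 1.0]}, [0.5, 0.5]
        )
        s = PatientSeries("p", {"HR": (np.array([0.0, 8.0]), np.array([0.0, 0.0]))})
        a = e_step(model, [s])[0]
        assert a.modal_group == 0
        assert a.posterior[0] >= 1 - 1e-6

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = make_model(
            {"TEMP": rng.normal(size=(4, 2))}, {"TEMP": rng.uniform(0.5, 2, 4)},
            rng.dirichlet(np.ones(4)),
        )
        for a in e_step(model, make_series(rng, n_patients=8, channels=("TEMP",))):
            assert a.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert a.max_posterior >= 1 / 4


class TestMStep:
    def test_single_group_reduces_to_ols(self):
        rng = np.random.default_rng(4)
        series = make_series(rng, n_patients=10, channels=("HR",))
        spec = GbtmSpec(n_groups=1, orders={"HR": 1})
        _, coefs, _ = m_step(series, np.ones((10, 1)), spec)
        t = np.concatenate([s.observed["HR"][0] for s in series])
        y = np.concatenate([s.observed["HR"][1] for s in series])
        beta_ols = np.polyfit(t, y, 1)[::-1]
        assert coefs["HR"][0] == pytest.approx(beta_ols, abs=1e-10)

    def test_hard_posteriors_reduce_to_subset_ols(self):
        rng = np.random.default_rng(5)
        series = make_series(rng, n_patients=12, channels=("HR",))
        post = np.zeros((12, 2))
        post[:6, 0] = 1.0
        post[6:, 1] = 1.0
        spec = GbtmSpec(n_groups=2, orders={"HR": 1})
        _, coefs, _ = m_step(series, post, spec)
        for g, subset in [(0, series[:6]), (1, series[6:])]:
            t = np.concatenate([s.observed["HR"][0] for s in subset])
            y = np.concatenate([s.observed["HR"][1] for s in subset])
            beta_ols = np.polyfit(t, y, 1)[::-1]
            assert coefs["HR"][g] == pytest.approx(beta_ols, abs=1e-10)

    def test_mixing_is_mean_posterior(self):
        rng = np.random.default_rng(6)
        series = make_series(rng, n_patients=9, channels=("HR",))
        post = rng.dirichlet(np.ones(3), size=9)
        spec = GbtmSpec(n_groups=3, orders={"HR": 1})
        mixing, _, _ = m_step(series, post, spec)
        assert mixing == pytest.approx(post.mean(axis=0))

    def test_singular_design_names_channel_and_group(self):
        # every observation at the same time: quadratic unidentifiable
        series = [
            PatientSeries(f"p{i}", {"RR": (np.array([4.0]), np.array([float(i)]))})
            for i in range(5)
        ]
        spec = GbtmSpec(n_groups=1, orders={"RR": 2})
        with pytest.raises(FitError, match="RR"):
            m_step(series, np.ones((5, 1)), spec)

    def test_shared_variance_pools_groups(self):
        rng = np.random.default_rng(7)
        series = make_series(rng, n_patients=10, channels=("HR",))
        post = rng.dirichlet(np.ones(2), size=10)
        spec_s = GbtmSpec(n_groups=2, orders={"HR": 1}, variance_mode="shared")
        _, _, sig = m_step(series, post, spec_s)
        assert sig["HR"][0] == sig["HR"][1]


class TestFit:
    def test_one_group_closed_form_in_two_iterations(self):
        rng = np.random.default_rng(8)
        series = make_series(rng, n_patients=10, channels=("HR", "TEMP"))
        model = fit(series, GbtmSpec(n_groups=1, orders={"HR": 1, "TEMP": 1}))
        assert model.converged and model.n_iter <= 2
        t = np.concatenate([s.observed["HR"][0] for s in series])
        y = np.concatenate([s.observed["HR"][1] for s in series])
        assert model.coefs["HR"][0] == pytest.approx(np.polyfit(t, y, 1)[::-1],
                                                     abs=1e-10)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(9)
        series = make_series(rng, n_patients=30, channels=("HR",))
        spec = GbtmSpec(n_groups=2, orders={"HR": 1})
        m1 = fit(series, spec, n_starts=4, seed=11)
        m2 = fit(series, spec, n_starts=4, seed=11)
        assert model_to_dict(m1) == model_to_dict(m2)

    def test_em_monotone_loglik_trace(self):
        rng = np.random.default_rng(10)
        series = make_series(rng, n_patients=25, channels=("HR", "TEMP"))
        model = fit(series, GbtmSpec(n_groups=2, orders={"HR": 1, "TEMP": 1}),
                    n_starts=3, seed=2)
        trace = np.asarray(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(12)
        n = 400
        series = []
        true_beta = {0: (0.0, 0.02), 1: (8.0, -0.02)}  # 8-sigma gap
        for i in range(n):
            g = int(i >= n * 0.4)  # 40/60 split
            b0, b1 = true_beta[g]
            t = np.sort(rng.uniform(0, 24, size=6))
            y = b0 + b1 * t + rng.normal(size=6)
            series.append(PatientSeries(f"p{i}", {"HR": (t, y)}))
        model = fit(series, GbtmSpec(n_groups=2, orders={"HR": 1}),
                    n_starts=5, seed=3)
        order = np.argsort(model.coefs["HR"][:, 0])
        mixing = model.mixing[order]
        assert mixing == pytest.approx([0.4, 0.6], abs=0.05)
        for g, idx in enumerate(order):
            est = model.coefs["HR"][idx]
            assert est[0] == pytest.approx(true_beta[g][0], abs=0.25)
            assert est[1] == pytest.approx(true_beta[g][1], abs=0.02)

    def test_all_starts_failing_is_fatal(self):
        series = [
            PatientSeries(f"p{i}", {"RR": (np.array([4.0]), np.array([float(i)]))})
            for i in range(6)
        ]
        with pytest.raises(FitError):
            fit(series, GbtmSpec(n_groups=2, orders={"RR": 2}), n_starts=2)

    def test_empty_series_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], GbtmSpec(n_groups=1, orders={"HR": 1}))


class TestBic:
    def test_hand_arithmetic(self):
        # loglik 0, 3 free parameters, n = e^2 -> BIC = 3 * 2 = 6
        model = make_model({"HR": [[0.0, 0.0]]}, {"HR": [1.0]}, [1.0])
        model.loglik = 0.0
        assert model.n_params == 3  # 2 mean coefs + 1 sigma, G=1
        assert bic(model, n_patients=math.e ** 2) == pytest.approx(6.0, abs=1e-12)

    def test_hand_arithmetic_integral_n(self):
        model = make_model({"HR": [[0.0, 0.0]]}, {"HR": [1.0]}, [1.0])
        model.loglik = 0.0
        model.n_patients = 100
        assert bic(model) == pytest.approx(3 * math.log(100))

    def test_extra_parameter_costs_ln_n(self):
        n = 250
        lin = make_model({"HR": [[0.0, 0.0]]}, {"HR": [1.0]}, [1.0])
        quad = make_model({"HR": [[0.0, 0.0, 0.0]]}, {"HR": [1.0]}, [1.0])
        lin.loglik = quad.loglik = -42.0
        assert bic(quad, n) - bic(lin, n) == pytest.approx(math.log(n))


class TestAveragePosteriorProbability:
    def test_hard_assignment_gives_one(self):
        a = [vt.PosteriorAssignment(f"p{i}", np.array([1.0, 0.0]), 0, 1.0)
             for i in range(3)]
        app = average_posterior_probability(a, 2)
        assert app[0] == pytest.approx(1.0)
        assert np.isnan(app[1])  # unpopulated group flagged

    def test_symmetric_posteriors_give_half(self):
        a = [vt.PosteriorAssignment(f"p{i}", np.array([0.5, 0.5]), 0, 0.5)
             for i in range(4)]
        app = average_posterior_probability(a, 2)
        assert app[0] == pytest.approx(0.5)


class TestInvariants:
    def test_label_permutation_leaves_likelihood_and_bic_unchanged(self):
        rng = np.random.default_rng(13)
        series = make_series(rng, n_patients=20, channels=("HR", "TEMP"))
        model = fit(series, GbtmSpec(n_groups=3, orders={"HR": 1, "TEMP": 1}),
                    n_starts=3, seed=5)
        perm = [2, 0, 1]
        permuted = permute_groups(model, perm)
        ll_orig = sum(patient_loglik(model, s)[1] for s in series)
        ll_perm = sum(patient_loglik(permuted, s)[1] for s in series)
        assert ll_perm == pytest.approx(ll_orig, abs=1e-9)
        assert bic(permuted) == pytest.approx(bic(model), abs=1e-9)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(14)
        series = make_series(rng, n_patients=15, channels=("HR",))
        model = fit(series, GbtmSpec(n_groups=2, orders={"HR": 1}),
                    n_starts=3, seed=6)
        restored = model_from_dict(model_to_dict(model))
        assert restored.mixing == pytest.approx(model.mixing)
        assert restored.coefs["HR"] == pytest.approx(model.coefs["HR"])
        assert restored.sigmas["HR"] == pytest.approx(model.sigmas["HR"])
        assert restored.loglik == pytest.approx(model.loglik)
        _, t1 = patient_loglik(restored, series[0])
        _, t2 = patient_loglik(model, series[0])
        assert t1 == pytest.approx(t2, abs=1e-12)
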