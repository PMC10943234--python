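"""Restarted-EM mixture fitting, labeling, override, and posteriors."""

import numpy as np
import pytest
from scipy.special import logsumexp

from freezescore.errors import DegenerateModelError, InputError
from freezescore.mixture import (
    COMPONENT_LABELS,
    MixtureConfig,
    MixtureModel,
    fit_mixture,
    manual_model,
    override_components,
    posterior_trace,
)
from freezescore.synthetic import SceneConfig, sample_schedule, simulate_trace
from freezescore.trace import SimilarityTrace

TRUE_MEANS = np.array([0.955, 0.975, 0.995])
TRUE_SDS = np.array([0.004, 0.004, 0.002])


def _three_cluster_trace(seed, n=9000, weights=(0.3, 0.3, 0.4)):
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=weights)
    x = rng.normal(TRUE_MEANS[comp], TRUE_SDS[comp])
    return SimilarityTrace(np.clip(x, 0, 1))


@pytest.fixture(scope="module")
def fitted():
    trace = _three_cluster_trace(0)
    return trace, fit_mixture(trace, MixtureConfig(n_restarts=60, seed=1))


class TestFit:
    def test_parameter_recovery(self, fitted):
        _, model = fitted
        assert np.abs(model.means - TRUE_MEANS).max() < 0.002
        assert np.abs(model.weights - [0.3, 0.3, 0.4]).max() < 0.05
        assert model.converged

    def test_constant_trace_raises_degeneracy(self):
        with pytest.raises(DegenerateModelError):
            fit_mixture(SimilarityTrace(np.full(200, 0.98)))

    def test_bimodal_data_carries_edge_case_warning(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(0.96, 0.003, 2000), rng.normal(0.995, 0.002, 2000)]
        )
        model = fit_mixture(
            SimilarityTrace(np.clip(x, 0, 1)), MixtureConfig(n_restarts=40, seed=0)
        )
        assert model.edge_case
        assert model.warnings

    def test_same_seed_bit_identical(self):
        trace = _three_cluster_trace(5, n=2000)
        cfg = MixtureConfig(n_restarts=20, seed=9)
        m1 = fit_mixture(trace, cfg)
        m2 = fit_mixture(trace, cfg)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.sds, m2.sds)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.log_likelihood == m2.log_likelihood

    def test_different_seeds_reach_same_optimum(self):
        trace = _three_cluster_trace(6, n=3000)
        lls = [
            fit_mixture(trace, MixtureConfig(n_restarts=30, seed=s)).log_likelihood
            for s in (1, 2)
        ]
        assert abs(lls[0] - lls[1]) <= 1e-4 * (1 + abs(lls[0]))

    def test_more_restarts_never_worse(self):
        trace = _three_cluster_trace(7, n=2000)
        ll1 = fit_mixture(trace, MixtureConfig(n_restarts=1, seed=3)).log_likelihood
        ll20 = fit_mixture(trace, MixtureConfig(n_restarts=20, seed=3)).log_likelihood
        assert ll20 >= ll1 - 1e-9

    def test_labels_are_a_permutation_by_ascending_mean(self, fitted):
        _, model = fitted
        assert sorted(model.labels.values()) == sorted(COMPONENT_LABELS)
        assert np.all(np.diff(model.means) > 0)
        assert model.labels[0] == "motion" and model.labels[2] == "freezing"

    def test_sklearn_cross_check(self, fitted):
        sklearn = pytest.importorskip("sklearn.mixture")
        trace, model = fitted
        gm = sklearn.GaussianMixture(
            n_components=3, n_init=10, random_state=0, tol=1e-6, reg_covar=1e-10
        ).fit(trace.scores.reshape(-1, 1))
        ref_means = np.sort(gm.means_.ravel())
        assert np.abs(model.means - ref_means).max() < 5e-4


class TestOverride:
    def test_override_sets_means_and_flag(self, fitted):
        _, model = fitted
        new = override_components(model, (0.90, 0.96, 0.99))
        assert new.manual_override
        assert new.means == pytest.approx([0.90, 0.96, 0.99])
        assert new.labels[2] == "freezing"

    def test_omitted_sds_and_weights_preserved(self, fitted):
        _, model = fitted
        new = override_components(model, (0.90, 0.96, 0.99))
        assert np.array_equal(new.sds, model.sds)
        assert np.array_equal(new.weights, model.weights)

    @pytest.mark.parametrize(
        "means", [(0.9, 0.9, 0.99), (0.5, 0.6, 1.5), (np.nan, 0.5, 0.9)]
    )
    def test_invalid_means_rejected(self, fitted, means):
        _, model = fitted
        with pytest.raises(InputError):
            override_components(model, means)

    def test_manual_model_defaults_pooled_sd_uniform_weights(self):
        trace = SimilarityTrace(np.full(100, 0.99))
        model = manual_model(trace, (0.90, 0.95, 0.99))
        assert model.manual_override
        assert np.allclose(model.weights, 1 / 3)
        assert np.all(model.sds > 0)

    def test_degenerate_all_still_trace_classifies_as_freezing(self):
        # the semi-automated contract: an animal that never moves is
        # scored by manual point estimates; every frame then lands in
        # the freezing component with posterior ~1
        trace = SimilarityTrace(np.full(300, 0.995))
        model = manual_model(trace, (0.90, 0.95, 0.995))
        post = posterior_trace(model, trace)
        assert np.all(post.freezing > 0.999)


class TestPosterior:
    def test_rows_sum_to_one_and_no_nan(self, fitted):
        trace, model = fitted
        extreme = SimilarityTrace(np.array([0.0, 1e-9, 0.5, 1.0]))
        for t in (trace, extreme):
            post = posterior_trace(model, t)
            assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.isfinite(post.probs))

    def test_dominant_component_at_freezing_mean(self, fitted):
        _, model = fitted
        post = posterior_trace(model, np.array([model.means[2]]))
        assert post.freezing[0] > 0.99

    def test_symmetry_between_equal_components(self):
        model = MixtureModel(
            weights=np.full(3, 1 / 3),
            means=np.array([0.2, 0.5, 0.8]),
            sds=np.full(3, 0.05),
        )
        post = posterior_trace(model, np.array([0.35]))  # midway 0.2-0.5
        assert post.motion[0] == pytest.approx(post.ambiguous[0], abs=1e-12)

    def test_matches_brute_force_densities(self, fitted):
        trace, model = fitted
        x = trace.scores[:1000]
        post = posterior_trace(model, SimilarityTrace(x))
        # independent direct density computation
        dens = np.empty((x.size, 3))
        for k in range(3):
            z = (x - model.means[k]) / model.sds[k]
            dens[:, k] = (
                model.weights[k]
                * np.exp(-0.5 * z * z)
                / (model.sds[k] * np.sqrt(2 * np.pi))
            )
        expected = dens / dens.sum(axis=1, keepdims=True)
        assert np.abs(post.probs - expected).max() < 1e-10

    def test_serialization_roundtrip(self, fitted, tmp_path):
        _, model = fitted
        p = model.save(tmp_path / "model.json")
        back = MixtureModel.load(p)
        assert np.allclose(back.means, model.means)
        assert back.converged == model.converged
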