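"""Tests for multi-dataset stacking and parameter-sharing schemes."""

import numpy as np
import pytest

import ionfit
from ionfit.fitting import FitOptions, jacobian, optimise
from ionfit.model import ModelParameters
from ionfit.multiobjective import (
    DatasetSpec,
    MultiFitProblem,
    SharingScheme,
    fit_multiobjective,
    global_parameter_layout,
    predict_rms,
    project,
)
from ionfit.protocols import StimulusProtocol, Trace, simulate
from ionfit.synthetic import generate_ap_dataset


def _names(n):
    return ModelParameters.from_vector(np.zeros(12 * n + 2)).parameter_names()


class TestLayout:
    def test_shared_keeps_base_count(self):
        names = _names(5)  # n = 62
        assert len(global_parameter_layout(names, 2, SharingScheme("shared"))) == 62

    def test_independent_multiplies(self):
        names = [f"p{k}" for k in range(10)]
        out = global_parameter_layout(names, 3, SharingScheme("independent"))
        assert len(out) == 30
        assert out[10] == "p0[1]"

    def test_mixed_adds_specific_blocks(self):
        names = _names(4)  # n = 50, as in the drug-block scenario
        scheme = SharingScheme("mixed", ("i3_g",))
        out = global_parameter_layout(names, 2, scheme)
        assert len(out) == 51
        assert out[-1] == "i3_g[1]"

    def test_unknown_specific_rejected(self):
        with pytest.raises(ValueError):
            global_parameter_layout(
                _names(1), 2, SharingScheme("mixed", ("nonexistent",))
            )

    def test_duplicate_specific_rejected(self):
        with pytest.raises(ValueError):
            SharingScheme("mixed", ("i1_g", "i1_g"))


class TestProject:
    def test_shared_identical_across_datasets(self):
        names = _names(1)
        gp = np.arange(14.0)
        scheme = SharingScheme("shared")
        for d in range(3):
            np.testing.assert_allclose(project(gp, d, scheme, names, 3), gp)

    def test_independent_own_block(self):
        names = ["a", "b"]
        gp = np.array([1.0, 2.0, 3.0, 4.0])
        scheme = SharingScheme("independent")
        np.testing.assert_allclose(project(gp, 1, scheme, names, 2), [3.0, 4.0])

    def test_mixed_differs_only_in_specific(self):
        names = _names(1)
        scheme = SharingScheme("mixed", ("i1_g",))
        gp = np.concatenate([np.arange(14.0) + 1.0, [99.0]])
        p0 = project(gp, 0, scheme, names, 2)
        p1 = project(gp, 1, scheme, names, 2)
        k = names.index("i1_g")
        assert p1[k] == 99.0
        mask = np.ones(14, bool)
        mask[k] = False
        np.testing.assert_allclose(p0[mask], p1[mask])

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            project(np.zeros(14), 2, SharingScheme("shared"), _names(1), 2)


@pytest.fixture(scope="module")
def paced_pair(one_current_model_module):
    """Two short paced synthetic datasets from the same one-current model."""
    params, x0 = one_current_model_module
    datasets = []
    for k, pi in enumerate((0.12, 0.16)):
        proto = StimulusProtocol.uniform(pi, 2, amplitude=25.0, first_onset=0.01)
        ds = generate_ap_dataset(
            params, x0, proto, duration=0.3, dt_out=1e-3, label=f"d{k}"
        )
        datasets.append(ds)
    return params, x0, datasets


@pytest.fixture(scope="module")
def one_current_model_module():
    from conftest import make_one_current_model

    return make_one_current_model()


class TestStackedResidual:
    def test_self_consistency_zero(self, paced_pair):
        params, x0, datasets = paced_pair
        prob = MultiFitProblem(datasets, SharingScheme("shared"), params)
        r = prob.residual(params.to_vector())
        assert r.size == sum(len(d.data) for d in datasets)
        assert np.max(np.abs(r)) < 1e-9

    def test_length_is_total_samples(self, paced_pair):
        params, x0, datasets = paced_pair
        t1 = Trace(datasets[0].data.t[:100], datasets[0].data.Em[:100])
        t2 = Trace(datasets[1].data.t[:50], datasets[1].data.Em[:50])
        d1 = DatasetSpec(t1, datasets[0].protocol, x0)
        d2 = DatasetSpec(t2, datasets[1].protocol, x0)
        prob = MultiFitProblem([d1, d2], SharingScheme("shared"), params)
        assert prob.residual(params.to_vector()).size == 150

    def test_shared_objective_is_sum_of_singles(self, paced_pair):
        params, x0, datasets = paced_pair
        vec = params.to_vector() * 1.05
        prob = MultiFitProblem(datasets, SharingScheme("shared"), params)
        total = np.sum(prob.residual(vec) ** 2)
        singles = 0.0
        for ds in datasets:
            single = MultiFitProblem([ds], SharingScheme("shared"), params)
            singles += np.sum(single.residual(vec) ** 2)
        assert total == pytest.approx(singles, rel=1e-12)

    def test_mixed_jacobian_block_structure(self, paced_pair):
        """In mixed mode with one data-specific parameter the stacked
        Jacobian has n + (R-1)S columns, and each dataset's rows have zero
        derivative with respect to the other dataset's copy."""
        params, x0, datasets = paced_pair
        scheme = SharingScheme("mixed", ("i1_g",))
        prob = MultiFitProblem(datasets, scheme, params)
        gp = prob.global_from_base(params.to_vector())
        n = params.n_parameters
        assert gp.size == n + 1
        J = jacobian(prob.residual, gp)
        assert J.shape[1] == n + 1
        m0 = len(datasets[0].data)
        k = prob.base_names.index("i1_g")
        col_norm = np.abs(J).max(axis=0)
        # dataset 1 rows vs the base copy of i1_g (owned by dataset 0)
        assert np.max(np.abs(J[m0:, k])) <= 1e-12 * max(col_norm[k], 1.0)
        # dataset 0 rows vs dataset 1's copy
        assert np.max(np.abs(J[:m0, n])) <= 1e-12 * max(col_norm[n], 1.0)


class TestFitting:
    def test_single_dataset_shared_equals_plain_optimise(self, paced_pair):
        params, x0, datasets = paced_pair
        p0 = params.to_vector() * 1.1
        opts = FitOptions(max_iterations=3, tol=1e-12)
        multi = fit_multiobjective(datasets[:1], SharingScheme("shared"), p0, params,
                                   options=opts)
        prob = MultiFitProblem(datasets[:1], SharingScheme("shared"), params)
        plain = optimise(prob.residual_function(), p0, opts)
        np.testing.assert_allclose(multi.fit.p, plain.p)

    def test_refit_from_own_output_converges_immediately(self, paced_pair):
        params, x0, datasets = paced_pair
        prob = MultiFitProblem(datasets[:1], SharingScheme("shared"), params)
        res = optimise(prob.residual_function(), params.to_vector(),
                       FitOptions(max_iterations=5))
        assert res.n_iterations == 0
        assert res.objective < 1e-15

    def test_two_truth_mixed_recovery(self, one_current_model_module):
        """Two datasets generated with different i1 conductances: a mixed
        fit with i1_g data-specific must recover conductances that differ
        in the right direction while shared entries stay shared."""
        params, x0 = one_current_model_module
        g_hi = params.currents[0].gmax  # 800
        g_lo = 0.6 * g_hi
        proto = StimulusProtocol.uniform(0.12, 2, amplitude=25.0, first_onset=0.01)
        low = params.with_conductances([g_lo])
        ds_hi = generate_ap_dataset(params, x0, proto, 0.3, dt_out=1e-3, label="hi")
        ds_lo = generate_ap_dataset(low, x0, proto, 0.3, dt_out=1e-3, label="lo")
        scheme = SharingScheme("mixed", ("i1_g",))
        prob = MultiFitProblem([ds_hi, ds_lo], scheme, params)
        p0 = prob.global_from_base(params.to_vector())
        k = prob.base_names.index("i1_g")
        p0[k] *= 0.85  # perturb both conductance copies
        p0[-1] *= 1.1
        res = optimise(prob.residual_function(), p0,
                       FitOptions(max_iterations=12, tol=1e-12))
        fit0 = project(res.p, 0, scheme, prob.base_names, 2)
        fit1 = project(res.p, 1, scheme, prob.base_names, 2)
        assert fit0[k] > fit1[k]  # right direction
        assert fit0[k] == pytest.approx(g_hi, rel=0.05)
        assert fit1[k] == pytest.approx(g_lo, rel=0.05)
        mask = np.ones(fit0.size, bool)
        mask[k] = False
        np.testing.assert_allclose(fit0[mask], fit1[mask])  # shared by construction

    def test_protocol_substitution_validation(self, paced_pair):
        """A frozen model simulates an unseen protocol: the validation-style
        prediction returns a finite RMS without touching parameters."""
        params, x0, datasets = paced_pair
        proto = StimulusProtocol.uniform(0.14, 2, amplitude=25.0, first_onset=0.01)
        unseen = generate_ap_dataset(params, x0, proto, 0.3, dt_out=1e-3)
        assert predict_rms(params, unseen) < 1e-9

    def test_optional_initial_state_fitting(self, paced_pair):
        """With fit_initial_states=True each dataset's starting state joins
        the global vector and a wrong starting potential is corrected."""
        params, x0, datasets = paced_pair
        prob = MultiFitProblem(datasets[:1], SharingScheme("shared"), params,
                               fit_initial_states=True)
        n = params.n_parameters
        assert prob.n_global() == n + params.n_states
        assert prob.layout()[n] == "x0_Em[0]"
        gp = prob.global_from_base(params.to_vector())
        assert np.max(np.abs(prob.residual(gp))) < 1e-9  # true states round-trip
        gp_bad = gp.copy()
        gp_bad[n] += 4.0  # wrong starting potential
        start_rms = np.sqrt(np.mean(prob.residual(gp_bad) ** 2))
        res = optimise(prob.residual_function(), gp_bad,
                       FitOptions(max_iterations=6, tol=1e-12))
        final_rms = np.sqrt(res.objective / len(datasets[0].data))
        assert final_rms < 0.2 * start_rms
        assert abs(res.p[n] - x0.Em) < 1.0

    def test_simulation_failure_names_dataset(self, paced_pair):
        params, x0, datasets = paced_pair
        prob = MultiFitProblem(datasets, SharingScheme("shared"), params)
        bad = params.to_vector()
        bad[:] = np.nan
        with pytest.raises(Exception, match="d0"):
            prob.residual(bad)
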