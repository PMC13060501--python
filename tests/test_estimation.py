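"""Model fitting, EBEs, shrinkage, RSEs and nested-model comparison."""

import numpy as np
import pandas as pd
import pytest

import poppk
from poppk import (FitResult, FitSettings, OneCompartmentModel, compute_ebes,
                   compute_rse, eta_shrinkage, fit_model, likelihood_ratio,
                   naive_initial_values, simulate_dataset)
from poppk.design import DoseGroup, StudyDesign
from poppk.likelihood import pack_dataset


def _dummy_result(ofv, names, params=None):
    return FitResult(
        params=params or poppk.published_parameters(), ofv=ofv, ofv_objective=ofv,
        param_names=names, fim=None, cov=None, se=None, rse=None,
        converged=True, n_subjects=10, n_obs=20,
        data_fingerprint=(10, 20, 1.0, 2.0))


FINAL_NAMES = ("cl_pop", "v_pop", "beta", "omega_cl", "omega_v", "error_b")
BASE_NAMES = ("cl_pop", "v_pop", "omega_cl", "omega_v", "error_b")


class TestInitialValues:
    def test_naive_init_lands_near_truth(self, dataset, truth):
        init = naive_initial_values(dataset, with_dose_covariate=True)
        assert init.cl_pop == pytest.approx(truth.cl_pop, rel=0.5)
        assert init.v_pop == pytest.approx(truth.v_pop, rel=0.5)
        assert -1.0 < init.beta < 0.2

    def test_base_model_init_has_zero_beta(self, dataset):
        init = naive_initial_values(dataset, with_dose_covariate=False)
        assert init.beta == 0.0


class TestFitModel:
    def test_low_noise_identifiability(self):
        """With tiny variability the fit recovers the generating fixed
        effects almost exactly."""
        gen = poppk.PopulationParameters(
            cl_pop=40.0, v_pop=50.0, beta=-0.4,
            omega_cl=0.0, omega_v=0.0, error_b=0.01)
        design = StudyDesign((
            DoseGroup(1.0, 4, (0.25, 1.0, 3.0), 0, ()),
            DoseGroup(10.0, 4, (0.25, 1.0, 3.0), 0, ()),
        ))
        data = simulate_dataset(design, gen, seed=21)
        fit = fit_model(data, settings=FitSettings(n_restarts=1))
        assert fit.params.cl_pop == pytest.approx(40.0, rel=0.02)
        assert fit.params.v_pop == pytest.approx(50.0, rel=0.02)
        assert fit.params.beta == pytest.approx(-0.4, abs=0.02)

    def test_single_dose_covariate_unidentifiable(self, truth):
        design = StudyDesign((DoseGroup(3.0, 3, (0.25, 1.0), 3, (2.0,)),))
        data = simulate_dataset(design, truth, seed=1)
        with pytest.raises(ValueError, match="unidentifiable|single"):
            OneCompartmentModel(data, dose_covariate=True)

    def test_fit_result_contract(self, fitted):
        assert np.isfinite(fitted.ofv)
        assert fitted.n_subjects == 70
        assert fitted.n_obs == 121
        assert fitted.with_dose_covariate
        assert fitted.param_names == FINAL_NAMES
        assert set(fitted.estimates()) == set(FINAL_NAMES)
        assert fitted.ebes is not None
        assert len(fitted.ebes.table) == 70
        text = fitted.summary()
        assert "OFV" in text and "cl_pop" in text

    def test_precision_matches_reported_scale(self, fitted):
        """Fixed effects are estimated with single-digit-percent RSEs
        under the study design, like the published analysis."""
        assert fitted.rse is not None
        assert 1.0 < fitted.rse["cl_pop"] < 15.0
        assert 1.0 < fitted.rse["v_pop"] < 20.0
        assert fitted.rse["beta"] < 30.0


class TestRse:
    def test_rse_table_flags_thresholds(self, fitted):
        table = compute_rse(fitted)
        row = table.set_index("parameter")
        assert row.loc["cl_pop", "rse_acceptable"]

    def test_duplicating_subjects_halves_information(self, dataset, fitted):
        """A dataset with every animal duplicated carries twice the
        information: RSEs shrink by ~sqrt(2)."""
        model = OneCompartmentModel(dataset)
        x = model._to_vector(fitted.params)
        t2 = dataset.table.copy()
        t2["ID"] = t2["ID"] + 1000
        doubled = poppk.PKDataset(pd.concat([dataset.table, t2],
                                            ignore_index=True))
        model2 = OneCompartmentModel(doubled)
        _, _, _, rse1 = model._uncertainty(x, fitted.params)
        _, _, _, rse2 = model2._uncertainty(x, fitted.params)
        for name in ("cl_pop", "v_pop", "beta"):
            assert rse2[name] == pytest.approx(rse1[name] / np.sqrt(2.0),
                                               rel=0.05)

    def test_base_model_excludes_beta(self, dataset, fast_settings):
        base = fit_model(dataset, with_dose_covariate=False,
                         settings=fast_settings)
        assert "beta" not in base.param_names
        assert "beta" not in compute_rse(base)["parameter"].tolist()
        assert base.params.beta == 0.0


class TestEbes:
    def test_typical_subject_has_zero_modes(self, truth):
        """Observations equal to typical predictions give eta_hat = 0
        (exact under additive error; the proportional model's log-SD term
        nudges the mode by O(omega^2))."""
        design = StudyDesign((DoseGroup(3.0, 2, (0.25, 1.0, 4.0), 0, ()),))
        data = simulate_dataset(design, truth.replace(omega_cl=0.0,
                                                      omega_v=0.0,
                                                      error_b=1e-9), seed=1)
        additive = poppk.PopulationParameters(
            cl_pop=truth.cl_pop, v_pop=truth.v_pop, beta=truth.beta,
            omega_cl=0.1, omega_v=0.1, error_a=2.0)
        ebes = compute_ebes(additive, data)
        np.testing.assert_allclose(ebes.table["eta_cl"], 0.0, atol=1e-5)
        np.testing.assert_allclose(ebes.table["eta_v"], 0.0, atol=1e-5)
        np.testing.assert_allclose(
            ebes.ipred.to_numpy(),
            data.observations["DV"].to_numpy(), rtol=1e-6)
        proportional = additive.replace(error_a=0.0, error_b=0.2)
        ebes_p = compute_ebes(proportional, data)
        np.testing.assert_allclose(ebes_p.table["eta_cl"], 0.0, atol=0.05)
        np.testing.assert_allclose(ebes_p.table["eta_v"], 0.0, atol=0.05)

    def test_degenerate_prior_pins_modes_at_zero(self, dataset, truth):
        tiny = truth.replace(omega_cl=1e-6, omega_v=1e-6)
        ebes = compute_ebes(tiny, dataset)
        assert np.max(np.abs(ebes.table[["eta_cl", "eta_v"]].to_numpy())) < 1e-3

    def test_dense_subject_recovers_generating_eta(self, truth):
        """20 observations with small error pin the individual clearance."""
        eta_cl_true, eta_v_true = 0.18, -0.12
        rng = np.random.default_rng(5)
        p = truth.replace(omega_cl=0.2, omega_v=0.2, error_b=0.05)
        cl = poppk.individual_clearance(p, 3.0, eta_cl_true)
        v = poppk.individual_parameter(p.v_pop, eta_v_true)
        times = np.linspace(0.1, 6.0, 20)
        f = poppk.predict_concentration(3.0, cl, v, times)
        y = f * (1 + 0.05 * rng.standard_normal(20))
        rows = [(1, 0.0, 3.0, 3.0, 0.0, 1)]
        rows += [(1, t, 0.0, 3.0, yy, 0) for t, yy in zip(times, y)]
        data = poppk.PKDataset(pd.DataFrame(
            rows, columns=["ID", "TIME", "AMT", "DOSE", "DV", "EVID"]))
        ebes = compute_ebes(p, data)
        assert ebes.table.loc[0, "eta_cl"] == pytest.approx(eta_cl_true,
                                                            abs=0.05 * 0.18 + 0.02)


class TestShrinkage:
    def test_total_shrinkage_when_modes_collapse(self):
        assert eta_shrinkage(np.zeros(10), omega=0.25) == pytest.approx(100.0)

    def test_zero_shrinkage_when_spread_matches_omega(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 1.0, 2000)
        eta = eta / np.std(eta, ddof=1) * 0.25
        assert eta_shrinkage(eta, omega=0.25) == pytest.approx(0.0, abs=1e-9)

    def test_variance_convention_exceeds_sd_convention(self):
        eta = np.array([-0.1, 0.0, 0.1, 0.05, -0.05])
        sd_based = eta_shrinkage(eta, omega=0.3, method="sd")
        var_based = eta_shrinkage(eta, omega=0.3, method="var")
        assert var_based > sd_based

    def test_zero_omega_rejected(self):
        with pytest.raises(ValueError):
            eta_shrinkage(np.zeros(5), omega=0.0)

    def test_shrinkage_grows_as_sampling_thins(self, truth):
        """Dense -> 3-sample -> single-sample designs give monotonically
        increasing clearance shrinkage at fixed parameters."""
        designs = [
            StudyDesign((DoseGroup(3.0, 100, tuple(np.linspace(0.1, 8, 12)), 0, ()),)),
            StudyDesign((DoseGroup(3.0, 100, (0.083, 0.5, 2.0), 0, ()),)),
            StudyDesign((DoseGroup(3.0, 0, (), 100, (0.25, 1.0, 3.0, 6.0, 8.0)),)),
        ]
        p = truth.replace(omega_cl=0.2, error_b=0.2)
        values = []
        for d in designs:
            data = simulate_dataset(d, p, seed=33)
            ebes = compute_ebes(p, data)
            values.append(eta_shrinkage(ebes, p.omega_cl, which="cl"))
        assert values[0] < values[1] < values[2]


class TestLikelihoodRatio:
    def test_boundary_is_inclusive(self):
        base = _dummy_result(103.84, BASE_NAMES)
        final = _dummy_result(100.00, FINAL_NAMES)
        delta, significant = likelihood_ratio(base, final)
        assert delta == pytest.approx(3.84)
        assert significant

    def test_below_cutoff_not_significant(self):
        base = _dummy_result(103.0, BASE_NAMES)
        final = _dummy_result(100.0, FINAL_NAMES)
        assert likelihood_ratio(base, final) == (3.0, False)

    def test_requires_single_extra_parameter(self):
        with pytest.raises(ValueError):
            likelihood_ratio(_dummy_result(10, FINAL_NAMES),
                             _dummy_result(9, FINAL_NAMES))

    def test_requires_same_dataset(self):
        base = _dummy_result(103.0, BASE_NAMES)
        final = _dummy_result(100.0, FINAL_NAMES)
        final.data_fingerprint = (9, 20, 1.0, 2.0)
        with pytest.raises(ValueError, match="different datasets"):
            likelihood_ratio(base, final)

    def test_nested_dominance_on_real_fits(self, dataset, fast_settings, fitted):
        """The final model initialised at the base optimum can only
        improve the deviance."""
        base = fit_model(dataset, with_dose_covariate=False,
                         settings=fast_settings)
        final = fit_model(dataset, with_dose_covariate=True,
                          init=base.params,
                          settings=fast_settings.replace(final_ofv="objective"))
        base_obj = base.ofv_objective
        assert base_obj - final.ofv_objective >= -1e-6


class TestSettingsValidation:
    def test_positive_tolerances_required(self):
        with pytest.raises(ValueError):
            FitSettings(xatol=0.0)

    def test_is_node_floor(self):
        with pytest.raises(ValueError):
            FitSettings(final_ofv="is", n_is_nodes=50)

    def test_unknown_error_model(self):
        with pytest.raises(ValueError):
            FitSettings(error_model="exponential")
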