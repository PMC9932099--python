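"""Shift prediction, global fitting, replicates and adequacy diagnostics."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import hostguest as hg
from hostguest.shift_fitting import _numeric_jacobian


class TestReferencing:
    def test_first_point_subtraction(self):
        raw = pd.DataFrame({"H3": [3.880, 3.900]})
        out = hg.reference_shifts(raw)
        assert list(out["H3"]) == pytest.approx([0.0, 0.020])

    def test_constant_raw_gives_zeros(self):
        raw = pd.DataFrame({"H3": [3.88] * 5, "H5": [3.70] * 5})
        assert np.allclose(hg.reference_shifts(raw).to_numpy(), 0.0)

    def test_reference_drift_is_removed_from_raw(self):
        # raw peak constant while the reference drifts +0.002 ppm
        raw = pd.DataFrame({"H3": [3.880, 3.880]})
        out = hg.reference_shifts(raw, reference_observed=[2.014, 2.016])
        assert list(out["H3"]) == pytest.approx([0.0, -0.002])

    def test_missing_first_point_rejected(self):
        raw = pd.DataFrame({"H3": [np.nan, 3.9]})
        with pytest.raises(ValueError):
            hg.reference_shifts(raw)


class TestPredictShifts:
    def test_dilute_host_fraction_bound(self):
        # [H]=[G]=1e-4, K=1e4: bound fraction = 0.381966 of the host
        m = hg.one_to_one_model(1e4)
        sens = hg.ShiftSensitivities({"H3": {"HG": 0.100}})
        dd = hg.predict_shifts(m, sens, [1e-4], [1e-4])
        assert dd["H3"].iloc[0] == pytest.approx(0.100 * (3.0 - math.sqrt(5.0)) / 2.0,
                                                 rel=1e-6)

    def test_saturation_reaches_sensitivity(self):
        m = hg.one_to_one_model(1e4)
        sens = hg.ShiftSensitivities({"H3": {"HG": 0.100}})
        dd = hg.predict_shifts(m, sens, [1e-4], [1.0])
        assert dd["H3"].iloc[0] == pytest.approx(0.100, abs=1e-4)

    def test_zero_guest_gives_zero(self):
        m = hg.self_competitive_model(1e5, 5e3)
        sens = hg.ShiftSensitivities({"H3": {"HG": 0.1, "H2": -0.1}})
        dd = hg.predict_shifts(m, sens, [5e-5, 5e-5], [0.0, 1e-4])
        assert dd["H3"].iloc[0] == 0.0

    def test_opposite_sign_equal_constant_states_cancel(self):
        m = hg.multi_orientation_model([1e4, 1e4])
        sens = hg.ShiftSensitivities({"H3": {"HG-1": 0.08, "HG-2": -0.08}})
        dd = hg.predict_shifts(m, sens, [1e-4] * 4, [0.0, 1e-5, 1e-4, 1e-3])
        assert np.allclose(dd["H3"].to_numpy(), 0.0, atol=1e-15)

    def test_zero_host_rejected(self):
        m = hg.one_to_one_model(1e4)
        sens = hg.ShiftSensitivities({"H3": {"HG": 0.1}})
        with pytest.raises(ValueError):
            hg.predict_shifts(m, sens, [0.0], [1e-4])


class TestGlobalFit:
    def test_noiseless_recovery(self, sbx_noiseless):
        spec, data = sbx_noiseless
        res = hg.fit_global(data, spec.model)
        assert res.converged and not res.rank_deficient
        assert res.constants["HG"] == pytest.approx(3.01e4, rel=1e-6)
        for p in data.proton_labels:
            assert res.sensitivities.get(p, "HG") == pytest.approx(
                spec.sensitivities.get(p, "HG"), rel=1e-6)

    def test_noisy_recovery_within_three_se(self, sbx_noisy):
        spec, data = sbx_noisy
        res = hg.fit_global(data, spec.model)
        K, se = res.constants["HG"], res.constant_errors["HG"]
        assert abs(K - 3.01e4) <= 3 * se

    def test_residuals_orthogonal_to_jacobian(self, sbx_noisy):
        spec, data = sbx_noisy
        res = hg.fit_global(data, spec.model)
        obs = data.shifts.to_numpy()[1:, :]

        def resid(x):
            constants = {"HG": math.exp(x[0])}
            sens = hg.ShiftSensitivities(
                {p: {"HG": x[1 + i]} for i, p in enumerate(data.proton_labels)})
            pred = hg.predict_shifts(spec.model.with_constants(constants), sens,
                                     data.total_host, data.total_guest).to_numpy()
            return (pred[1:, :] - obs).ravel()

        x = np.array([math.log(res.constants["HG"])]
                     + [res.sensitivities.get(p, "HG") for p in data.proton_labels])
        r = resid(x)
        J = _numeric_jacobian(resid, x)
        g = J.T @ r
        assert np.all(np.abs(g) <= 1e-6 * max(np.linalg.norm(r), 1.0))

    def test_invariant_to_proton_relabeling(self, sbx_noisy):
        spec, data = sbx_noisy
        res = hg.fit_global(data, spec.model)
        perm = ["H6", "H1", "H5", "H3"]
        data2 = hg.TitrationDataset(data.total_host, data.total_guest,
                                    data.shifts[perm], data.temperature)
        res2 = hg.fit_global(data2, spec.model)
        assert res2.constants["HG"] == pytest.approx(res.constants["HG"], rel=1e-8)

    def test_invariant_to_concentration_unit_rescaling(self, sbx_noisy):
        spec, data = sbx_noisy
        res_M = hg.fit_global(data, spec.model)
        scale = 1e3  # express concentrations in mM; K then comes out in mM^-1
        data_mM = hg.TitrationDataset(data.total_host * scale, data.total_guest * scale,
                                      data.shifts, data.temperature)
        res_mM = hg.fit_global(data_mM, spec.model.with_constants({"HG": 30.1}))
        assert res_mM.constants["HG"] * scale == pytest.approx(res_M.constants["HG"],
                                                               rel=1e-6)

    def test_too_few_points_rejected(self):
        G = np.array([0.0, 1e-5, 2e-5])
        shifts = pd.DataFrame({"H3": [0.0, 0.01, 0.02]})
        data = hg.TitrationDataset(np.full(3, 1e-4), G, shifts)
        with pytest.raises(hg.FitError, match="too few"):
            hg.fit_global(data, hg.one_to_one_model(1e4))

    def test_degenerate_two_orientation_model_flagged(self):
        """Two 1:1 orientations cannot be told apart: rank-deficiency flagged."""
        m2 = hg.multi_orientation_model([44e3, 2.1e3])
        sens = hg.ShiftSensitivities({
            "H1": {"HG-1": -0.02, "HG-2": 0.01},
            "H3": {"HG-1": -0.11, "HG-2": -0.05},
            "H5": {"HG-1": -0.14, "HG-2": 0.06},
            "H6": {"HG-1": 0.03, "HG-2": -0.04},
        })
        spec = hg.ScenarioSpec(host="deg", model=m2, sensitivities=sens,
                               host_total=2e-5, noise_sd=0.001, replicates=1, seed=7)
        data = hg.generate_titration(spec)[0]
        try:
            res = hg.fit_global(data, m2)
        except hg.FitError as exc:
            res = exc.best_result
        assert res is not None and res.rank_deficient
        assert any(f.startswith("rank_deficient") for f in res.flags)


class TestTwoStateFit:
    def test_noiseless_exact_recovery(self):
        spec = replace(hg.get_scenario("SBX+1-two-state"), noise_sd=0.0, replicates=1)
        data = hg.generate_titration(spec)[0]
        res = hg.fit_two_state(data, "self-competitive")
        assert res.constants["HG"] == pytest.approx(67e3, rel=1e-6)
        assert res.constants["H2"] == pytest.approx(2.5e3, rel=1e-6)

    def test_simple_data_collapses_secondary_state(self, sbx_noiseless):
        _, data = sbx_noiseless
        try:
            res = hg.fit_two_state(data, "self-competitive")
        except hg.FitError as exc:
            res = exc.best_result
        assert res is not None
        low_pop = any(f.startswith("low_secondary_population") for f in res.flags)
        # either the H2 state's population collapses or its constant is
        # reported with essentially no precision
        se2 = res.constant_errors["H2"]
        vague = (not np.isfinite(se2)) or se2 > 10 * res.constants["H2"]
        assert low_pop or vague or res.rank_deficient

    def test_unknown_variant_rejected(self, sbx_noiseless):
        _, data = sbx_noiseless
        with pytest.raises(ValueError, match="variant"):
            hg.fit_two_state(data, "three-state")

    def test_assignment_caveat_reported(self):
        spec = replace(hg.get_scenario("SBX-two-state"), replicates=1)
        data = hg.generate_titration(spec)[0]
        res = hg.fit_two_state(data, "self-competitive")
        assert any(f.startswith("orientation_assignment_external") for f in res.flags)
        K1, K2 = hg.two_state_constants(res)
        assert K1 > 0 and K2 > 0

    @pytest.mark.parametrize("variant", ["HG2", "H2G"])
    def test_alternative_variants_noiseless_round_trip(self, variant):
        factory = {"HG2": hg.host_guest2_model, "H2G": hg.host2_guest_model}[variant]
        lab2 = {"HG2": "HG2", "H2G": "H2G"}[variant]
        model = factory(5e4, 4e3)
        sens = hg.ShiftSensitivities({
            p: {"HG": v, lab2: w} for p, (v, w) in
            {"H1": (-0.02, -0.09), "H3": (-0.11, -0.12),
             "H5": (-0.14, 0.11), "H6": (0.03, 0.09)}.items()})
        spec = hg.ScenarioSpec(host="alt", model=model, sensitivities=sens,
                               host_total=5e-5, n_points=16, noise_sd=0.0,
                               replicates=1, seed=5,
                               schedule=np.concatenate([[0.0],
                                                        np.geomspace(5e-6, 4e-4, 15)]))
        data = hg.generate_titration(spec)[0]
        res = hg.fit_two_state(data, variant, init={"constants": {"K1": 2e4, "K2": 1e3}})
        K1, K2 = hg.two_state_constants(res)
        assert K1 == pytest.approx(5e4, rel=1e-5)
        assert K2 == pytest.approx(4e3, rel=1e-5)


class TestReplicates:
    def test_mean_and_sample_sd(self):
        """K values 28.0, 30.0, 32.3 mM^-1 average to 30.1 +/- 2.15 mM^-1."""
        spec = replace(hg.get_scenario("SBX"), noise_sd=0.0, replicates=1)
        data = hg.generate_titration(spec)[0]
        results = []
        for K in (28.0e3, 30.0e3, 32.3e3):
            r = hg.fit_global(data, spec.model)
            r.model = r.model.with_constants({"HG": K})
            results.append(r)
        summary = hg.aggregate_replicates(results)
        assert summary.constants.loc["HG", "mean"] == pytest.approx(30.1e3)
        assert summary.constants.loc["HG", "sd"] == pytest.approx(
            math.sqrt(9.26 / 2) * 1e3, rel=1e-9)
        assert summary.n_replicates == 3

    def test_identical_replicates_have_zero_sd(self, sbx_noiseless):
        spec, data = sbx_noiseless
        r = hg.fit_global(data, spec.model)
        summary = hg.aggregate_replicates([r, r])
        assert summary.constants.loc["HG", "sd"] == 0.0

    def test_single_result_rejected(self, sbx_noiseless):
        spec, data = sbx_noiseless
        r = hg.fit_global(data, spec.model)
        with pytest.raises(ValueError):
            hg.aggregate_replicates([r])

    def test_mixed_models_rejected(self, sbx_noiseless):
        spec, data = sbx_noiseless
        r1 = hg.fit_global(data, spec.model)
        ts = replace(hg.get_scenario("SBX-two-state"), replicates=1)
        r2 = hg.fit_two_state(hg.generate_titration(ts)[0])
        with pytest.raises(ValueError, match="different models"):
            hg.aggregate_replicates([r1, r2])

    def test_full_triplicate_pipeline(self):
        spec = hg.get_scenario("SBX")
        fits = [hg.fit_global(d, spec.model) for d in hg.generate_titration(spec)]
        summary = hg.aggregate_replicates(fits)
        mean = summary.constants.loc["HG", "mean"]
        sd = summary.constants.loc["HG", "sd"]
        assert mean == pytest.approx(3.01e4, rel=0.2)
        assert sd >= 0.0


class TestModelAdequacy:
    def test_monotonic_simple_data_adequate(self, sbx_noisy):
        spec, data = sbx_noisy
        res = hg.fit_global(data, spec.model)
        assert hg.model_adequacy(data, res).verdict == "simple_adequate"

    def test_engineered_sign_reversal_flags_simple_model(self):
        """A proton whose two bound states shift in opposite directions
        produces a non-monotonic curve that a 1:1 model cannot describe."""
        model = hg.host_guest2_model(5e4, 8e3)
        sens = hg.ShiftSensitivities({
            "H1": {"HG": -0.02, "HG2": -0.02},
            "H3": {"HG": -0.11, "HG2": -0.02},
            "H5": {"HG": 0.10, "HG2": -0.35},  # sign reversal driver
            "H6": {"HG": 0.03, "HG2": 0.05},
        })
        spec = hg.ScenarioSpec(host="rev", model=model, sensitivities=sens,
                               host_total=5e-5, noise_sd=0.0005, replicates=1, seed=4,
                               schedule=np.concatenate([[0.0],
                                                        np.geomspace(5e-6, 1e-3, 15)]))
        data = hg.generate_titration(spec)[0]
        fs = hg.fit_global(data, hg.one_to_one_model(5e4))
        report = hg.model_adequacy(data, fs)
        assert report.verdict == "two_state_preferred"
        assert report.per_proton.loc["H5", "non_monotonic"]

    def test_pure_noise_supports_no_model(self, pure_noise_dataset):
        res = hg.fit_global(pure_noise_dataset, hg.one_to_one_model(1e4))
        report = hg.model_adequacy(pure_noise_dataset, res)
        assert report.verdict == "no_binding"

    def test_rss_comparison_reported(self):
        spec = replace(hg.get_scenario("SBX+1-two-state"), replicates=1)
        data = hg.generate_titration(spec)[0]
        fs = hg.fit_global(data, hg.one_to_one_model(6.7e4))
        ft = hg.fit_two_state(data)
        report = hg.model_adequacy(data, fs, ft)
        assert report.rss_two_state == ft.rss
        assert report.rss_ratio == pytest.approx(fs.rss / ft.rss)


class TestDatasetValidation:
    def test_first_point_must_be_guest_free(self):
        with pytest.raises(ValueError, match="guest-free"):
            hg.TitrationDataset(np.full(3, 1e-4), np.array([1e-6, 2e-6, 3e-6]),
                                pd.DataFrame({"H3": [0.0, 0.01, 0.02]}))

    def test_guest_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            hg.TitrationDataset(np.full(3, 1e-4), np.array([0.0, 2e-6, 2e-6]),
                                pd.DataFrame({"H3": [0.0, 0.01, 0.02]}))

    def test_first_shifts_must_be_zero(self):
        with pytest.raises(ValueError, match="zero"):
            hg.TitrationDataset(np.full(3, 1e-4), np.array([0.0, 1e-6, 2e-6]),
                                pd.DataFrame({"H3": [0.005, 0.01, 0.02]}))
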