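"""1:1 mass balance, isotherm fitting, and bootstrap uncertainty."""

import numpy as np
import pytest
from scipy.optimize import brentq

from clampmap.binding import (
    BindingIsothermModel,
    BindingModelParams,
    NoBindingError,
    bootstrap_uncertainty,
    bound_fraction,
    fit_binding,
    predict_observed_shift,
    trajectories_to_design,
)
from clampmap.io import match_titration_peaks
from clampmap.synthetic import GeneratorSpec, gen_titration_dataset


def brute_force_fraction(P, L, Kd):
    """Independent oracle: root of the mass-balance polynomial
    (P - x)(L - x) = Kd * x solved numerically for the complex x."""
    if L == 0:
        return 0.0
    f = lambda x: (P - x) * (L - x) - Kd * x
    x = brentq(f, 0.0, min(P, L), xtol=1e-16, rtol=1e-15)
    return x / P


class TestBoundFraction:
    def test_no_ligand_gives_zero(self):
        assert bound_fraction(50.0, 0.0, 1.0) == 0.0

    def test_tight_binding_stoichiometric_limit(self):
        assert bound_fraction(50.0, 100.0, 1e-3) == pytest.approx(1.0, abs=1e-4)

    def test_symmetric_mid_affinity_case(self):
        # golden-ratio value of the quadratic at P = L = Kd
        assert bound_fraction(10.0, 10.0, 10.0) == pytest.approx(0.38197, abs=1e-5)

    def test_agrees_with_numeric_mass_balance_on_grid(self):
        grid = [1.0, 10.0, 100.0, 1000.0]
        kds = [0.1, 1.0, 10.0, 100.0, 1000.0]
        for P in grid:
            for L in grid:
                for Kd in kds:
                    assert bound_fraction(P, L, Kd) == pytest.approx(
                        brute_force_fraction(P, L, Kd), abs=1e-10
                    )

    def test_monotone_in_ligand_and_affinity(self):
        P = 25.0
        Ls = np.linspace(0, 500, 60)
        f = bound_fraction(P, Ls, 5.0)
        assert np.all(np.diff(f) >= -1e-14)
        for L in (1.0, 30.0, 300.0):
            f_kd = [bound_fraction(P, L, kd) for kd in (0.1, 1, 10, 100, 1000)]
            assert np.all(np.diff(f_kd) <= 1e-14)

    @pytest.mark.parametrize("P,L,Kd", [(-1, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_invalid_inputs(self, P, L, Kd):
        with pytest.raises(ValueError):
            bound_fraction(P, L, Kd)


class TestPredictShift:
    def test_zero_fraction_and_saturation_limits(self):
        params = BindingModelParams(K_d=10.0, delta_max={7: 0.25})
        assert predict_observed_shift(params, 10.0, 0.0, 7) == 0.0
        assert predict_observed_shift(params, 10.0, 1e9, 7) == pytest.approx(0.25, rel=1e-4)

    def test_product_of_oracle_values(self):
        params = BindingModelParams(K_d=10.0, delta_max={7: 0.25})
        assert predict_observed_shift(params, 10.0, 10.0, 7) == pytest.approx(
            0.09549, abs=1e-5
        )

    def test_unknown_residue(self):
        params = BindingModelParams(K_d=10.0, delta_max={7: 0.25})
        with pytest.raises(KeyError):
            predict_observed_shift(params, 10.0, 10.0, 8)


class TestFitting:
    def test_noiseless_global_recovery(self):
        spec = GeneratorSpec(
            seed=1, K_d_true=5.0, noise_csp=0.0,
            delta_max_map={401: 0.08, 402: 0.12, 403: 0.16, 404: 0.2, 405: 0.24, 406: 0.3},
        )
        traj = match_titration_peaks(gen_titration_dataset(spec))
        X, y = trajectories_to_design(traj, spec.P_tot)
        model = BindingIsothermModel().fit(X, y)
        assert model.converged_
        assert model.K_d_ == pytest.approx(5.0, rel=1e-4)
        for res, true_amp in spec.delta_max_map.items():
            assert model.delta_max_[res] == pytest.approx(true_amp, rel=1e-3)

    def test_noisy_recovery_median_over_replicates(self):
        # study conditions: K_d 3.27 uM, P 10 uM, noise 0.004 ppm
        kds = []
        for seed in range(30):
            spec = GeneratorSpec(seed=seed)
            traj = match_titration_peaks(gen_titration_dataset(spec))
            X, y = trajectories_to_design(traj, spec.P_tot)
            kds.append(BindingIsothermModel().fit(X, y).K_d_)
        assert np.median(kds) == pytest.approx(3.27, rel=0.15)

    def test_all_zero_csp_raises_no_binding(self, spec):
        traj = match_titration_peaks(gen_titration_dataset(spec))
        X, y = trajectories_to_design(traj, spec.P_tot)
        with pytest.raises(NoBindingError):
            BindingIsothermModel().fit(X, np.zeros_like(y))

    def test_log_kd_bias_vanishes_with_noise(self):
        biases = []
        for noise in (0.004, 0.0004, 0.0):
            spec = GeneratorSpec(seed=9, noise_csp=noise)
            traj = match_titration_peaks(gen_titration_dataset(spec))
            X, y = trajectories_to_design(traj, spec.P_tot)
            kd = BindingIsothermModel().fit(X, y).K_d_
            biases.append(abs(np.log10(kd / spec.K_d_true)))
        assert biases[-1] < 1e-4
        assert biases[-1] <= biases[0]

    def test_per_residue_mode(self):
        spec = GeneratorSpec(seed=2, noise_csp=0.0)
        traj = match_titration_peaks(gen_titration_dataset(spec))
        X, y = trajectories_to_design(traj, spec.P_tot, residue_subset=set(spec.delta_max_map))
        model = BindingIsothermModel(mode="per-residue").fit(X, y)
        for res in spec.delta_max_map:
            assert model.K_d_[res] == pytest.approx(spec.K_d_true, rel=1e-3)

    def test_sklearn_param_interface(self):
        model = BindingIsothermModel(mode="per-residue")
        assert model.get_params()["mode"] == "per-residue"
        model.set_params(mode="global")
        assert model.mode == "global"


class TestBootstrap:
    @staticmethod
    def _fitted(seed=3, **kw):
        spec = GeneratorSpec(seed=seed, **kw)
        traj = match_titration_peaks(gen_titration_dataset(spec))
        X, y = trajectories_to_design(traj, spec.P_tot)
        return BindingIsothermModel().fit(X, y), X, y

    def test_deterministic_for_fixed_seed(self):
        model, X, y = self._fitted()
        a = bootstrap_uncertainty(model, X, y, n_boot=30, seed=42)
        b = bootstrap_uncertainty(model, X, y, n_boot=30, seed=42)
        assert a.interval == b.interval
        assert a.K_d_stderr == b.K_d_stderr

    def test_noiseless_data_give_tiny_stderr(self):
        model, X, y = self._fitted(noise_csp=0.0)
        boot = bootstrap_uncertainty(model, X, y, n_boot=30, seed=0)
        assert boot.K_d_stderr < 1e-6 * model.K_d_

    def test_n_boot_floor(self):
        model, X, y = self._fitted()
        with pytest.raises(ValueError):
            bootstrap_uncertainty(model, X, y, n_boot=5)

    def test_interval_coverage_of_generating_kd(self):
        # 90% percentile interval should cover the generating K_d in >= 80%
        # of seeded trials under the study noise conditions
        hits = 0
        n_trials = 40
        for seed in range(n_trials):
            spec = GeneratorSpec(seed=100 + seed)
            traj = match_titration_peaks(gen_titration_dataset(spec))
            X, y = trajectories_to_design(traj, spec.P_tot)
            model = BindingIsothermModel().fit(X, y)
            boot = bootstrap_uncertainty(model, X, y, n_boot=60, seed=seed)
            if boot.interval[0] <= spec.K_d_true <= boot.interval[1]:
                hits += 1
        assert hits >= 0.8 * n_trials


class TestTightBindingDiagnostics:
    def test_saturated_titration_flagged_poorly_determined(self):
        # P/K_d > 100 with every nonzero point past one equivalent: K_d is
        # unidentifiable and the fit must say so rather than report a number
        flagged = 0
        for seed in range(5):
            spec = GeneratorSpec(
                seed=seed, K_d_true=3.27, P_tot=350.0,
                ratios=(0.0, 2.0, 3.0, 5.0, 8.0),
            )
            traj = match_titration_peaks(gen_titration_dataset(spec))
            res = fit_binding(traj, 350.0, n_boot=60, seed=seed)
            if res.poorly_determined or not res.converged:
                flagged += 1
        assert flagged >= 4

    def test_identifiable_titration_not_flagged(self):
        spec = GeneratorSpec(seed=1)
        traj = match_titration_peaks(gen_titration_dataset(spec))
        res = fit_binding(traj, spec.P_tot, n_boot=60, seed=1)
        assert res.converged and not res.poorly_determined
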