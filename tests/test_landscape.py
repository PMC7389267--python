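"""Two-regime mean-force model, landscape derivation, and fitting tests."""

import warnings

import numpy as np
import pytest

import dfskit as dk
from dfskit.constants import EULER_GAMMA

RATES = dk.default_loading_rates()


class TestMeanForce:
    def test_zero_rate_gives_equilibrium_force(self):
        assert dk.fndy_mean_force(0.0, 36.2, 67.4, 732.4) == 36.2

    def test_analytic_point_at_crossover_scale(self):
        f_eq, f_beta, k_off = 50.0, 80.0, 500.0
        r = np.exp(EULER_GAMMA) * k_off * f_beta
        expected = f_eq + f_beta * np.log(2.0)
        assert dk.fndy_mean_force(r, f_eq, f_beta, k_off) == pytest.approx(expected, rel=1e-12)

    def test_monotone_concave_with_equilibrium_plateau(self):
        r = np.linspace(0.0, 1e6, 2000)
        F = dk.fndy_mean_force(r, 36.2, 67.4, 732.4)
        assert np.all(np.diff(F) > 0)          # strictly increasing in r
        assert np.all(np.diff(F, 2) < 1e-9)    # concave in r
        assert dk.fndy_mean_force(1e-9, 36.2, 67.4, 732.4) == pytest.approx(36.2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dk.fndy_mean_force(100.0, -1.0, 67.4, 732.4)
        with pytest.raises(ValueError):
            dk.fndy_mean_force(-5.0, 36.2, 67.4, 732.4)


class TestDeriveLandscape:
    def test_bond_lifetime_from_dissociation_rate(self):
        derived = dk.derive_landscape(36.2, 67.4, 732.4, k_c=10.0)
        assert round(derived.tau0_ms, 2) == 1.37

    def test_barrier_width_inversion(self):
        derived = dk.derive_landscape(36.2, 67.42, 732.4, k_c=10.0)
        assert derived.x_t_A == pytest.approx(0.600, abs=5e-4)

    def test_binding_free_energy(self):
        derived = dk.derive_landscape(88.1, 404.75, 113.6, k_c=10.0)
        # |dG| = 88.1^2 / (2*10) = 388.08 pN*nm = 55.86 kcal/mol, reported negative
        assert derived.delta_g_kcal_per_mol == pytest.approx(-55.86, abs=0.01)

    def test_missing_spring_constant_warns_and_omits(self):
        with pytest.warns(UserWarning, match="k_c"):
            derived = dk.derive_landscape(36.2, 67.4, 732.4)
        assert derived.delta_g_kcal_per_mol is None
        assert derived.tau0_ms == pytest.approx(1000.0 / 732.4)


class TestFit:
    @staticmethod
    def _noiseless(ref):
        F = dk.fndy_mean_force(RATES, ref.f_eq_pN, ref.f_beta_pN, ref.k_off_per_s)
        return dk.DFSDataset(RATES, F)

    def test_noiseless_self_consistency(self, reference_landscape):
        ref = reference_landscape
        fit = dk.fit_fndy(self._noiseless(ref), spring_constant=10.0)
        assert fit.f_eq == pytest.approx(ref.f_eq_pN, rel=5e-3)
        assert fit.f_beta == pytest.approx(ref.f_beta_pN, rel=5e-3)
        assert fit.k_off == pytest.approx(ref.k_off_per_s, rel=5e-3)
        assert fit.converged

    def test_binned_matches_unbinned_on_noiseless_data(self, reference_landscape):
        # one bin per distinct rate: binning must then be lossless
        ref = reference_landscape
        data = self._noiseless(ref)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse bins warn
            unbinned = dk.fit_fndy(data, spring_constant=10.0)
            binned = dk.fit_fndy(data, spring_constant=10.0, binned=True, n_bins=len(RATES))
        for a, b in [
            (binned.f_eq, unbinned.f_eq),
            (binned.f_beta, unbinned.f_beta),
            (binned.k_off, unbinned.k_off),
        ]:
            assert a == pytest.approx(b, rel=5e-3)

    def test_derived_identities_hold_exactly(self, reference_landscape):
        ref = reference_landscape
        fit = dk.fit_fndy(self._noiseless(ref), spring_constant=12.0)
        kBT = dk.thermal_energy(fit.temperature)
        assert fit.tau0 == pytest.approx(1000.0 / fit.k_off, rel=1e-12)
        assert fit.x_t == pytest.approx(10.0 * kBT / fit.f_beta, rel=1e-12)
        pn_nm = -fit.delta_g * 6.9477
        assert pn_nm == pytest.approx(fit.f_eq**2 / (2 * 12.0), rel=1e-9)

    def test_zero_rate_spread_warns(self):
        r = np.full(20, 1000.0)
        F = dk.fndy_mean_force(r, 36.2, 67.4, 732.4) + np.random.default_rng(0).normal(0, 5, 20)
        with pytest.warns(UserWarning, match="poorly conditioned"):
            dk.FNdYModel().fit(dk.DFSDataset(r, F))

    def test_stochastic_recovery_single_replicate(self):
        """f_eq and k_off recovered from one simulated spectrum."""
        data = dk.sample_rupture_forces(
            f_eq=88.1, f_beta=404.75, k_off=113.6, seed=42, n_per_rate=167
        )
        fit = dk.fit_fndy(data)
        assert fit.f_eq == pytest.approx(88.1, rel=0.05)
        assert max(fit.k_off / 113.6, 113.6 / fit.k_off) < 2.0

    def test_confidence_intervals_bracket_estimate(self):
        data = dk.sample_rupture_forces(
            f_eq=36.2, f_beta=67.4, k_off=732.4, seed=3, n_per_rate=100
        )
        model = dk.FNdYModel().fit(data)
        for name, value in [("f_eq", model.f_eq_), ("f_beta", model.f_beta_), ("k_off", model.k_off_)]:
            lo, hi = model.ci99_[name]
            assert lo <= value <= hi

    def test_prediction_band_covers_mean_curve(self):
        data = dk.sample_rupture_forces(
            f_eq=36.2, f_beta=67.4, k_off=732.4, seed=4, n_per_rate=100
        )
        model = dk.FNdYModel().fit(data)
        lo, hi = model.prediction_interval(RATES)
        mid = model.predict(RATES)
        assert np.all(lo < mid) and np.all(mid < hi)

    def test_sklearn_params_round_trip(self):
        model = dk.FNdYModel(spring_constant=15.0, binned=True)
        clone_params = model.get_params()
        assert clone_params["spring_constant"] == 15.0
        model.set_params(binned=False)
        assert not model.binned


class TestBinning:
    def test_partition(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(100, 20000, 1200)
        F = dk.fndy_mean_force(r, 36.2, 67.4, 732.4) + rng.normal(0, 10, 1200)
        data = dk.bin_dfs(dk.DFSDataset(r, np.abs(F) + 1.0), n_bins=8)
        assert len(data.bins) <= 8
        assert (data.bins["n"] >= 1).all()
        assert data.bins["n"].sum() == 1200
        assert data.bins["loading_rate"].is_monotonic_increasing

    def test_few_distinct_rates_warn_and_fewer_bins(self):
        rng = np.random.default_rng(1)
        r = rng.choice([100.0, 200.0, 300.0, 500.0, 900.0], 40)
        F = np.full(40, 50.0) + np.abs(rng.normal(0, 1, 40))
        with pytest.warns(UserWarning):
            data = dk.bin_dfs(dk.DFSDataset(r, F), n_bins=8)
        assert len(data.bins) < 8

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="n_bins"):
            dk.bin_dfs(dk.DFSDataset([100.0, 200.0, 400.0], [30.0, 35.0, 40.0]), n_bins=2)
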