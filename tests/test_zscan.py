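"""Signal-model arithmetic: normalisation, U-ratio, K and sigma extraction,
lifetime collapse, and the unit-conversion identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotorscan import (
    PhotophysicsParams,
    SurfaceAdsorptionModel,
    ZScanProfile,
    collapse_Rtau,
    compute_U,
    coverage_fraction,
    estimate_K,
    mono_ratio,
    normalize_profile,
    sigma_from_K,
    tube_partition_ratio,
)
from rotorscan.synthetic import GroundTruth, simulate_zscan
from rotorscan.zscan import MOLAR_TO_PER_UM3, per_depth_K

PHOT = PhotophysicsParams(phi_b=0.15, tau_b=0.12, phi_s=0.15, tau_s=1.7)
DEPTHS = (5.0, 7.0, 10.0, 20.0, 30.0)


def _u_series(values, z=None):
    z = np.asarray([0.0, 5.0, 7.0, 10.0, 20.0, 30.0] if z is None else z, dtype=float)
    return pd.Series(np.asarray(values, dtype=float), index=z)


def _model_u(k, phi00, r_th):
    return (1.0 + k * phi00 * np.asarray(r_th)) / (1.0 + k * phi00)


class TestNormalise:
    @pytest.mark.parametrize(
        "intensity, expected",
        [([100.0, 100.0, 100.0], [1.0, 1.0, 1.0]), ([50.0, 60.0, 70.0], [1.0, 1.2, 1.4])],
    )
    def test_division_anchor(self, intensity, expected):
        prof = ZScanProfile(z_f=[0.0, 5.0, 10.0], intensity=intensity)
        assert normalize_profile(prof).values == pytest.approx(expected)

    def test_zero_anchor_rejected(self):
        prof = ZScanProfile(z_f=[0.0, 5.0], intensity=[0.0, 10.0])
        with pytest.raises(ValueError, match="anchor"):
            normalize_profile(prof)

    def test_missing_interface_rejected(self):
        with pytest.raises(ValueError, match="z_f = 0"):
            ZScanProfile(z_f=[1.0, 5.0], intensity=[1.0, 1.0])


class TestURatio:
    def test_identical_curves_give_unity(self):
        h = _u_series([1.0, 1.2, 1.3, 1.4, 1.5, 1.6])
        assert compute_U(h, h).values == pytest.approx(np.ones(6))

    def test_forward_model_asymptote(self):
        """With K = 5 µm and phi00 = 0.2 µm⁻¹, U decreases towards
        U_inf = 1/(1 + 1) = 0.5 as R_th -> 0."""
        r_th = np.array([1.0, 0.2, 0.1, 0.05, 0.005, 0.0])
        u = _model_u(5.0, 0.2, r_th)
        assert u[0] == pytest.approx(1.0)
        assert np.all(np.diff(u) < 0)
        assert u[-1] == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        a = _u_series(np.ones(6))
        b = pd.Series(np.ones(5), index=[0.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="same z_F grid"):
            compute_U(a, b)

    def test_noisy_excess_flagged_not_clipped(self):
        i_n = _u_series([1.0, 1.21, 1.3, 1.4, 1.5, 1.6])
        h = _u_series([1.0, 1.2, 1.3, 1.4, 1.5, 1.6])
        with pytest.warns(UserWarning, match="exceed 1"):
            u = compute_U(i_n, h)
        assert u.values[1] > 1.0  # retained


class TestEstimateK:
    def test_no_surface_excess(self):
        u = _u_series(np.ones(6))
        k, sd = estimate_K(u, phi00=0.2, depths=DEPTHS)
        assert k == 0.0 and sd == 0.0

    def test_worked_asymptote(self):
        u = _u_series([1.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        k, _ = estimate_K(u, phi00=0.2, depths=DEPTHS)
        assert k == pytest.approx(5.0)

    @given(
        k=st.floats(min_value=0.0, max_value=1.0e3),
        phi00=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_asymptotic_round_trip_exact(self, k, phi00):
        """Plugging the exact asymptote U_inf = (1 + phi00 K)^-1 back into the
        estimator returns K to machine precision."""
        u_inf = 1.0 / (1.0 + phi00 * k)
        u = _u_series(np.concatenate([[1.0], np.full(5, u_inf)]))
        k_hat, sd = estimate_K(u, phi00=phi00, depths=DEPTHS)
        assert k_hat == pytest.approx(k, rel=1e-12, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-9 * max(k, 1.0))

    def test_corrected_inversion_exact_at_finite_depth(self):
        """The R_th-corrected estimator recovers K exactly from noiseless
        finite-depth U values where the asymptotic form is biased."""
        k_true, phi00 = 80.0, 0.25
        r_th = np.array([0.2, 0.12, 0.06, 0.015, 0.007])
        u = _u_series(np.concatenate([[1.0], _model_u(k_true, phi00, r_th)]))
        k_asym, _ = estimate_K(u, phi00=phi00, depths=DEPTHS)
        k_corr, _ = estimate_K(u, phi00=phi00, depths=DEPTHS, r_th=r_th)
        assert k_corr == pytest.approx(k_true, rel=1e-10)
        assert abs(k_asym - k_true) / k_true > 0.3  # asymptotic bias is real

    def test_zero_u_rejected(self):
        u = _u_series([1.0, 0.5, 0.0, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="positive"):
            estimate_K(u, phi00=0.2, depths=DEPTHS)

    def test_empty_depths_rejected(self):
        u = _u_series(np.ones(6))
        with pytest.raises(ValueError, match="empty"):
            estimate_K(u, phi00=0.2, depths=())

    def test_noise_above_one_maps_to_zero(self):
        u = _u_series([1.0, 1.02, 0.5, 0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="U > 1"):
            table = per_depth_K(u, phi00=0.2, depths=DEPTHS)
        assert table.loc[5.0, "K_i"] == 0.0


class TestSigmaConversion:
    def test_zero_k(self):
        sigma, sd = sigma_from_K(0.0, 1e-7, PHOT)
        assert sigma == 0.0 and sd == 0.0

    def test_unit_conversion_oracle(self):
        """K = 1 µm at 1e-7 M with identical photophysics: sigma equals the
        number density 1e-7 * N_A / 1e15 = 60.2214 µm⁻³ times 1 µm."""
        sigma, _ = sigma_from_K(1.0, 1e-7, PHOT)
        assert sigma == pytest.approx(60.2214076, rel=1e-6)

    def test_linear_uncertainty(self):
        sigma, sd = sigma_from_K(2.0, 1e-7, PHOT, k_sd=0.5)
        assert sd / sigma == pytest.approx(0.25)

    @given(
        k1=st.floats(min_value=0.01, max_value=100.0),
        factor=st.floats(min_value=1.01, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_sigma_strictly_increasing_in_k(self, k1, factor):
        s1, _ = sigma_from_K(k1, 1e-7, PHOT)
        s2, _ = sigma_from_K(k1 * factor, 1e-7, PHOT)
        assert s2 > s1

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_K(-1.0, 1e-7, PHOT)
        with pytest.raises(ValueError):
            sigma_from_K(1.0, -1e-7, PHOT)


class TestWorkedExamples:
    def test_tube_partition_printed_example(self):
        """sigma = 1e-2 nm⁻² (= 1e4 µm⁻²), rho = 1e-6 M, r = 100 µm gives
        2 sigma/(r rho) ~ 0.33, i.e. ~0.3 to one significant figure."""
        ratio = tube_partition_ratio(1.0e4, 1.0e-6, 100.0)
        hand = 2.0 * 1.0e4 / (100.0 * 1.0e-6 * MOLAR_TO_PER_UM3)
        assert ratio == pytest.approx(hand, rel=1e-6)
        assert round(ratio, 1) == 0.3

    def test_tube_partition_scalings(self):
        base = tube_partition_ratio(1.0e4, 1.0e-6, 100.0)
        assert tube_partition_ratio(1.0e4, 1.0e-6, 200.0) == pytest.approx(base / 2.0)
        assert tube_partition_ratio(0.0, 1.0e-6, 100.0) == 0.0
        with pytest.raises(ValueError):
            tube_partition_ratio(1.0, 1.0e-6, 0.0)

    @pytest.mark.parametrize(
        "sigma, s_mol, expected",
        [(3300.0, 1.0, 0.0033), (1.0e4, 1.0, 0.01), (0.0, 1.0, 0.0)],
    )
    def test_coverage_fraction(self, sigma, s_mol, expected):
        assert coverage_fraction(sigma, s_mol) == pytest.approx(expected)


class TestLifetimeCollapse:
    def test_linear_rescaling(self):
        prof = pd.Series([1.7, 1.2, 0.7], index=[0.0, 5.0, 20.0])
        r = collapse_Rtau(prof, tau_b=0.7)
        assert r.values == pytest.approx([1.0, 0.5, 0.0])

    def test_degenerate_surface_rejected(self):
        prof = pd.Series([0.7, 0.7, 0.7], index=[0.0, 5.0, 20.0])
        with pytest.raises(ValueError, match="no detectable surface species"):
            collapse_Rtau(prof, tau_b=0.7)

    def test_collapse_is_condition_independent(self, dr_water):
        """Lifetime profiles generated from one depth response with different
        (tau_S, tau_B, K) collapse onto each other after the R_tau rescaling
        and the monoexponential correction."""
        r_th = dr_water.r_th
        z = dr_water.z_f_grid
        recovered = []
        for tau_s, tau_b, k in [(1.7, 0.12, 50.0), (1.6, 0.5, 10.0), (1.7, 0.9, 200.0)]:
            p = PhotophysicsParams(phi_b=0.1, tau_b=tau_b, phi_s=0.15, tau_s=tau_s)
            x = k * dr_water.phi00 * r_th  # surface/bulk intensity ratio
            tau = (x + 1.0) / (x / tau_s + 1.0 / tau_b)
            r_tau = collapse_Rtau(pd.Series(tau, index=z), tau_b)
            recovered.append(r_tau * mono_ratio(r_tau, k, dr_water.phi00, p).values)
        for other in recovered[1:]:
            assert np.allclose(recovered[0].values, other.values, rtol=1e-9)

    def test_mono_ratio_limits(self):
        r_tau = pd.Series([1.0, 0.5, 0.0], index=[0.0, 5.0, 30.0])
        assert mono_ratio(r_tau, 0.0, 0.2, PHOT).values == pytest.approx([1.0, 1.0, 1.0])
        assert mono_ratio(r_tau, 7.0, 0.2, PHOT).values[0] == pytest.approx(1.0)

    def test_mono_ratio_recovers_rth_from_mixture(self, dr_water):
        """Two monoexponential species mixed with ray-traced weights: forming
        <tau> per depth, rescaling to R_tau, and applying the monoexponential
        relation recovers the ray-traced R_th."""
        k = 40.0
        p = PHOT
        x = k * dr_water.phi00 * dr_water.r_th
        tau = (x + 1.0) / (x / p.tau_s + 1.0 / p.tau_b)
        r_tau = collapse_Rtau(pd.Series(tau, index=dr_water.z_f_grid), p.tau_b)
        r_th_rec = r_tau.values * mono_ratio(r_tau, k, dr_water.phi00, p).values
        assert np.allclose(r_th_rec, dr_water.r_th, rtol=0.02)


class TestModelFit:
    def test_hydrophilic_profile_matches_H(self, dr_water):
        """A surface-free (sigma = 0) noiseless scan is exactly the
        homogeneous rise H, so U is identically 1 and sigma fits to 0."""
        gt = GroundTruth(sigma_true=0.0, photophysics=PHOT, noise_cv=0.0, seed=1)
        prof = simulate_zscan(dr_water, gt, surface_kind="hydrophilic")
        i_n = normalize_profile(prof)
        assert np.allclose(i_n.values, dr_water.h_pred, rtol=1e-12)
        res = SurfaceAdsorptionModel(
            prof, depth_response=dr_water, photophysics=PHOT
        ).fit()
        assert res.sigma == pytest.approx(0.0, abs=1e-9)

    def test_results_self_consistent(self, dr_water):
        gt = GroundTruth(sigma_true=500.0, photophysics=PHOT, noise_cv=0.0, seed=2)
        prof = simulate_zscan(dr_water, gt)
        res = SurfaceAdsorptionModel(prof, depth_response=dr_water, photophysics=PHOT).fit()
        assert res.u_inf == pytest.approx(1.0 / (1.0 + res.phi00_used * res.k_value))
        assert res.sigma == pytest.approx(gt.sigma_true, rel=1e-6)
        text = res.summary()
        assert "sigma" in text and "per-depth" in text

    def test_k_recovery_with_noise(self, dr_water):
        """Round trip at K_true ~ 2 µm with 1% multiplicative noise recovers
        K well within 15%."""
        p = PhotophysicsParams(phi_b=0.15, tau_b=0.12, phi_s=0.15, tau_s=1.7)
        sigma_true = 2.0 * 1e-7 * MOLAR_TO_PER_UM3  # K_true = 2 µm
        gt = GroundTruth(sigma_true=sigma_true, photophysics=p, noise_cv=0.01, seed=5)
        prof = simulate_zscan(dr_water, gt)
        res = SurfaceAdsorptionModel(prof, depth_response=dr_water, photophysics=p).fit()
        assert res.k_value == pytest.approx(2.0, rel=0.15)

    def test_missing_reference_and_depth_response_rejected(self):
        prof = ZScanProfile(z_f=[0.0, 5.0], intensity=[1.0, 1.0])
        with pytest.raises(ValueError, match="reference"):
            SurfaceAdsorptionModel(prof, photophysics=PHOT)
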