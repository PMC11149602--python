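import numpy as np
import pytest

from nprm.bootstrap import (
    build_dgp,
    bootstrap_maps,
    dgp_diagnostics,
    generate_replicate,
    mip_and_se,
)
from nprm.fit import fit_tacs
from nprm.frames import FitWeights
from nprm.image import embed


@pytest.fixture(scope="module")
def fitted_phantom(truth_basis, short_schedule, short_weights):
    """Noisy voxel curves plus their basis fits, for DGP construction."""
    rng = np.random.default_rng(21)
    mu = truth_basis.frame_matrix(0.0)
    n = 400
    organ = rng.integers(0, 3, n)
    amp = rng.uniform(0.5, 2.0, n)
    clean = amp[:, None] * mu[:, organ].T
    # per-voxel noise scale variation gives the SE maps real structure
    scale = rng.uniform(0.3, 3.0, n)
    sigma = 0.05 * clean.max()
    z = clean + sigma * scale[:, None] * rng.standard_normal(clean.shape)
    fits = fit_tacs(z, truth_basis, short_weights, [0.0])
    return z, fits


class TestBuildDGP:
    def test_perfect_fit_degenerate(self, short_weights):
        z = np.random.default_rng(0).gamma(2.0, 1.0, (50, short_weights.w.size))
        dgp = build_dgp(z, z, short_weights)
        assert dgp.sigma_e == 0.0
        np.testing.assert_allclose(dgp.psi, 1.0)
        np.testing.assert_allclose(dgp.phi, 1.0)
        np.testing.assert_allclose(dgp.eps, 0.0)

    def test_normalization_constraints(self, fitted_phantom, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        assert np.mean(dgp.psi**2) == pytest.approx(1.0, rel=1e-6)
        assert np.sum(short_weights.w * dgp.phi**2) == pytest.approx(1.0, rel=1e-6)
        pool_rms = np.sqrt(np.mean(dgp.eps**2 @ short_weights.w))
        assert pool_rms == pytest.approx(1.0, rel=1e-6)

    def test_planted_factor_recovery(self):
        rng = np.random.default_rng(11)
        # J large enough that per-voxel MAD noise does not bias sigma_e
        N, J = 10_000, 200
        w = FitWeights(np.ones(J))
        a = rng.uniform(0.5, 2.0, N)
        b = rng.uniform(0.5, 2.0, J)
        a /= np.sqrt(np.mean(a**2))
        b /= np.sqrt(np.mean(b**2))
        e = 2.0 * a[:, None] * b[None, :] * rng.standard_normal((N, J))
        dgp = build_dgp(np.zeros((N, J)) + e, np.zeros((N, J)), w)
        assert dgp.sigma_e == pytest.approx(2.0, rel=0.03)
        rel_phi = np.abs(dgp.phi / b - 1.0)
        assert np.median(rel_phi) < 0.03 and rel_phi.max() < 0.08
        # per-voxel psi has MAD noise at J = 30; check aggregate alignment
        ratio = dgp.psi / a
        assert np.median(ratio) == pytest.approx(1.0, rel=0.03)
        assert np.corrcoef(dgp.psi, a)[0, 1] > 0.9

    def test_scale_equivariance(self, fitted_phantom, short_weights):
        z, fits = fitted_phantom
        d1 = build_dgp(z, fits, short_weights)
        e = z - fits.fitted
        d2 = build_dgp(fits.fitted + 2.0 * e, fits, short_weights)
        assert d2.sigma_e == pytest.approx(2.0 * d1.sigma_e, rel=1e-6)
        np.testing.assert_allclose(d2.psi, d1.psi, rtol=1e-6)
        np.testing.assert_allclose(d2.phi, d1.phi, rtol=1e-6)


class TestGenerateReplicate:
    def test_zero_sigma_exact(self, fitted_phantom, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(fits.fitted, fits, short_weights)
        rep = generate_replicate(dgp, seed=1)
        np.testing.assert_array_equal(rep, fits.fitted)

    def test_bit_reproducible(self, fitted_phantom, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        np.testing.assert_array_equal(
            generate_replicate(dgp, seed=7), generate_replicate(dgp, seed=7)
        )
        assert np.any(generate_replicate(dgp, 7) != generate_replicate(dgp, 8))

    def test_moment_match(self, short_weights):
        rng = np.random.default_rng(3)
        N, J = 300, short_weights.w.size
        fitted = rng.gamma(2.0, 1.0, (N, J))
        a = rng.uniform(0.5, 2.0, N)  # real per-voxel scale structure
        e = 0.3 * a[:, None] * rng.standard_normal((N, J))
        dgp = build_dgp(fitted + e, fitted, short_weights)
        reps = np.stack([generate_replicate(dgp, s) for s in range(200)])
        sd = reps.std(axis=0)
        target = dgp.sigma_e * dgp.psi[:, None] * dgp.phi[None, :]
        # per-cell SD over 200 replicates carries ~15% Monte-Carlo noise,
        # but resampling respects the scale structure in aggregate
        assert np.mean(sd) == pytest.approx(np.mean(target), rel=0.1)
        assert np.corrcoef(sd.ravel(), target.ravel())[0, 1] > 0.5

    def test_skewness_preserved(self, short_weights):
        from scipy.stats import skew

        rng = np.random.default_rng(9)
        N, J = 2000, short_weights.w.size
        fitted = np.ones((N, J))
        k = 4.0 / 1.5**2  # gamma with skewness 1.5
        e = 0.2 * (rng.gamma(k, 1.0, (N, J)) - k) / np.sqrt(k)
        dgp = build_dgp(fitted + e, fitted, short_weights)
        rep = generate_replicate(dgp, seed=4)
        got = skew((rep - fitted).ravel())
        assert got == pytest.approx(skew(e.ravel()), abs=0.2)


class TestBootstrapMaps:
    def test_zero_sigma_zero_se(self, fitted_phantom, truth_basis, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(fits.fitted, fits, short_weights)
        _, se = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=3, seed=0, delta_grid_s=[0.0]
        )
        for name in ("V_b", "V_d", "K_d", "K_i"):
            np.testing.assert_allclose(se[name], 0.0, atol=1e-12)

    def test_seed_reproducible(self, fitted_phantom, truth_basis, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        _, se1 = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=4, seed=5, delta_grid_s=[0.0]
        )
        _, se2 = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=4, seed=5, delta_grid_s=[0.0]
        )
        np.testing.assert_array_equal(se1["K_i"], se2["K_i"])

    def test_nb_too_small_rejected(self, fitted_phantom, truth_basis, short_weights):
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        with pytest.raises(ValueError):
            bootstrap_maps(z, truth_basis, short_weights, dgp, N_B=1)

    def test_voi_se_below_mean_voxel_se(self, fitted_phantom, truth_basis, short_weights):
        """Averaging reduces noise: the SD of the VOI-mean K_i across
        replicates is below the mean voxel-level SE."""
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        ens, se = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=12, seed=3, delta_grid_s=[0.0]
        )
        ki = ens.stack("K_i")  # (N_B, N)
        voi_se = np.nanstd(np.nanmean(ki, axis=1), ddof=1)
        assert voi_se < np.nanmean(se["K_i"])


    def test_nb_sensitivity(self, fitted_phantom, truth_basis, short_weights):
        """SE maps at N_B = 25 and N_B = 100 agree closely (correlation > 0.9)."""
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        _, se25 = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=25, seed=1, delta_grid_s=[0.0]
        )
        _, se100 = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=100, seed=2, delta_grid_s=[0.0]
        )
        assert np.corrcoef(se25["K_i"], se100["K_i"])[0, 1] > 0.9

    def test_disjoint_seed_sets_agree_within_chi_error(
        self, fitted_phantom, truth_basis, short_weights
    ):
        """SEs from disjoint seeds differ by no more than chi-distribution
        sampling noise of an SD at the given N_B."""
        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        nb = 40
        _, se_a = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=nb, seed=11, delta_grid_s=[0.0]
        )
        _, se_b = bootstrap_maps(
            z, truth_basis, short_weights, dgp, N_B=nb, seed=12, delta_grid_s=[0.0]
        )
        log_ratio = np.log(se_a["K_i"] / se_b["K_i"])
        # SD of log(SE) ~ 1/sqrt(2(N_B - 1)) per run; difference has sqrt(2) more
        expected_sd = np.sqrt(2.0) / np.sqrt(2 * (nb - 1))
        assert np.std(log_ratio) < 2.0 * expected_sd


class TestMipAndSe:
    def test_constant_map(self):
        pm = np.full((4, 4, 3), 2.5)
        reps = [pm.copy() for _ in range(5)]
        mip, mip_se = mip_and_se(pm, reps, axis=2)
        np.testing.assert_allclose(mip, 2.5)
        np.testing.assert_allclose(mip_se, 0.0)

    def test_single_bright_voxel(self):
        rng = np.random.default_rng(0)
        reps = []
        vals = []
        for _ in range(30):
            m = np.zeros((3, 3, 4))
            v = 10.0 + rng.normal()
            vals.append(v)
            m[1, 1, 2] = v
            reps.append(m)
        point = np.zeros((3, 3, 4))
        point[1, 1, 2] = 10.0
        mip, mip_se = mip_and_se(point, reps, axis=2)
        assert mip_se[1, 1] == pytest.approx(np.std(vals, ddof=1))

    def test_order_statistic_inflation_two_voxel(self):
        """Max of two noisy voxels varies even where each voxel's own SD is
        small relative to the projected maximum's variation."""
        rng = np.random.default_rng(1)
        reps = []
        for _ in range(400):
            m = np.zeros((1, 1, 2))
            m[0, 0, 0] = 1.0 + 0.1 * rng.standard_normal()
            m[0, 0, 1] = 1.0 + 0.1 * rng.standard_normal()
            reps.append(m)
        point = np.ones((1, 1, 2))
        _, mip_se = mip_and_se(point, reps, axis=2)
        maxes = [r.max() for r in reps]
        assert mip_se[0, 0] == pytest.approx(np.std(maxes, ddof=1), rel=1e-9)
        # the max of two iid normals has smaller SD than either coordinate
        assert 0.0 < mip_se[0, 0] < 0.1

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            mip_and_se(np.zeros((2, 2, 2)), [np.zeros((2, 2, 2))], axis=5)


class TestDiagnostics:
    def test_white_noise_acf_fwhm(self, short_weights):
        rng = np.random.default_rng(2)
        shape = (12, 12, 12)
        mask = np.ones(shape, bool)
        N, J = int(np.prod(shape)), short_weights.w.size
        fitted = np.ones((N, J))
        e = 0.1 * rng.standard_normal((N, J))
        dgp = build_dgp(fitted + e, fitted, short_weights)
        diags = dgp_diagnostics(dgp, mask=mask)
        fwhm = diags["acf"].groupby("axis")["fwhm_voxels"].first()
        assert np.all(fwhm < 1.5)

    def test_smoothed_field_fwhm(self, short_weights):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(4)
        shape = (24, 24, 24)
        mask = np.ones(shape, bool)
        J = short_weights.w.size
        kernel_fwhm = 3.0
        sd = kernel_fwhm / 2.3548
        eps4 = rng.standard_normal(shape + (J,))
        eps4 = gaussian_filter(eps4, sigma=(sd, sd, sd, 0.0), mode="wrap")
        e = 0.1 * eps4.reshape(-1, J)
        fitted = np.ones((np.prod(shape), J))
        dgp = build_dgp(fitted + e, fitted, short_weights)
        diags = dgp_diagnostics(dgp, mask=mask, frames=list(range(6)))
        fwhm = diags["acf"].groupby("axis")["fwhm_voxels"].first()
        # white noise smoothed with a gaussian has ACF FWHM = sqrt(2)*kernel
        expect = np.sqrt(2.0) * kernel_fwhm
        assert np.all(np.abs(fwhm - expect) / expect < 0.15)

    def test_axial_psi_profile(self, short_weights):
        rng = np.random.default_rng(6)
        shape = (6, 6, 10)
        mask = np.ones(shape, bool)
        J = short_weights.w.size
        z_prof = 1.0 + 1.0 * (2 * np.arange(shape[2]) / (shape[2] - 1) - 1) ** 2
        psi_vol = np.broadcast_to(z_prof, shape)
        e = psi_vol[..., None] * 0.2 * rng.standard_normal(shape + (J,))
        fitted = np.ones((np.prod(shape), J))
        dgp = build_dgp(fitted + e.reshape(-1, J), fitted, short_weights)
        prof = dgp_diagnostics(dgp, mask=mask)["axial_profile"]
        corr = np.corrcoef(prof["mean_psi"], z_prof)[0, 1]
        assert corr > 0.9

    def test_dose_correlation_planted(self, fitted_phantom, short_weights):
        import pandas as pd

        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        rng = np.random.default_rng(8)
        dose = np.linspace(1.0, 5.0, 12)
        table = pd.DataFrame(
            {"dose": dose, "sigma_e": 0.3 * dose + 0.05 * rng.standard_normal(12)}
        )
        out = dgp_diagnostics(dgp, study_table=table)["dose_scale"]
        assert out["correlation"].iloc[0] > 0.95

    def test_single_study_flagged(self, fitted_phantom, short_weights):
        import pandas as pd

        z, fits = fitted_phantom
        dgp = build_dgp(z, fits, short_weights)
        out = dgp_diagnostics(
            dgp, study_table=pd.DataFrame({"dose": [1.0], "sigma_e": [0.1]})
        )["dose_scale"]
        assert np.isnan(out["correlation"].iloc[0])
        assert "undefined" in out["flag"].iloc[0]
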