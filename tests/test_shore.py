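"""3D-SHORE fitting and EAP indices against Gaussian-propagator oracles."""

import numpy as np
import pytest

from gmshore.acquisition import AcquisitionScheme, sphere_points
from gmshore.cohort import TissueCompartment, simulate_signal
from gmshore.maps import compute_index_maps
from gmshore.shore import (
    ShoreIndexEngine,
    estimate_shore_scale,
    fit_shore,
    shore_index_list,
    shore_indices,
    shore_matrix,
)

TAU = 0.025


def _signal(scheme, evals, s0=100.0):
    return simulate_signal(
        [TissueCompartment(np.diag(np.asarray(evals, dtype=float)), 1.0)], scheme, s0)


def gaussian_oracle(evals, tau=TAU):
    """Closed-form EAP indices of a Gaussian propagator, axis = e1."""
    l1, l2, l3 = evals
    return {
        "rtop": (4 * np.pi * tau) ** -1.5 / np.sqrt(l1 * l2 * l3),
        "rtap": (4 * np.pi * tau) ** -1.0 / np.sqrt(l2 * l3),
        "rtpp": (4 * np.pi * tau) ** -0.5 / np.sqrt(l1),
        "msd": 2 * tau * (l1 + l2 + l3),
    }


@pytest.fixture(scope="module")
def dense_scheme():
    """Six-shell scheme rich enough to determine all 50 coefficients."""
    dirs = sphere_points(30)
    bvals = [0.0] * 4
    bvecs = [[0.0, 0.0, 0.0]] * 4
    for b in (400, 800, 1200, 1600, 2000, 2400):
        bvals += [float(b)] * 30
        bvecs += dirs.tolist()
    return AcquisitionScheme(bvals, np.array(bvecs))


class TestBasis:
    def test_coefficient_count_nmax6(self):
        """Independent count: SHO states with 2n - l <= 6, l even."""
        expected = sum(
            2 * l + 1
            for n in range(0, 7)
            for l in range(0, n + 1, 2)
            if 2 * n - l <= 6
        )
        assert expected == 50
        assert len(shore_index_list(6)) == 50

    def test_matrix_shape_and_b0_columns(self, scheme):
        phi = shore_matrix(scheme, zeta=700.0, tau=TAU)
        assert phi.shape == (103, 50)
        idx = shore_index_list(6)
        b0 = scheme.b0_mask
        for j, (n, l, m) in enumerate(idx):
            if l > 0:
                assert np.allclose(phi[b0, j], 0.0)

    def test_invalid_radial_order(self):
        with pytest.raises(ValueError, match="even"):
            shore_index_list(5)


class TestFitShore:
    def test_isotropic_coefficients_spherical(self, scheme):
        """Isotropic Gaussian: all l>0 coefficients vanish."""
        fit = fit_shore(_signal(scheme, [1e-3] * 3), scheme, tau=TAU)
        l_arr = np.array([l for (_, l, _) in fit.indices])
        l0_energy = np.sqrt(np.sum(fit.coeffs[l_arr == 0] ** 2))
        assert np.all(np.abs(fit.coeffs[l_arr > 0]) < 1e-6 * l0_energy)

    def test_round_trip_known_coefficients(self, dense_scheme):
        """Refit of a basis-generated signal recovers coefficients to 1e-8."""
        rng = np.random.default_rng(5)
        zeta = 700.0
        phi = shore_matrix(dense_scheme, zeta, TAU)
        c_true = rng.standard_normal(50) * np.exp(-np.arange(50) / 12)
        c_true[0] = 3.0  # keep b0 amplitude positive
        signal = phi @ c_true
        assert signal[dense_scheme.b0_mask].mean() > 0
        fit = fit_shore(signal, dense_scheme, zeta=zeta, tau=TAU,
                        lambda_n=0.0, lambda_l=0.0)
        b0 = signal[dense_scheme.b0_mask].mean()
        assert np.allclose(fit.coeffs * b0, c_true, atol=1e-8)

    def test_underdetermined_without_regularization(self, scheme):
        """Two shells cannot determine 50 coefficients without a penalty."""
        with pytest.raises(ValueError, match="underdetermined"):
            fit_shore(_signal(scheme, [1e-3] * 3), scheme, zeta=700.0,
                      tau=TAU, lambda_n=0.0, lambda_l=0.0)

    def test_invalid_zeta(self, scheme):
        with pytest.raises(ValueError, match="zeta"):
            fit_shore(_signal(scheme, [1e-3] * 3), scheme, zeta=-1.0, tau=TAU)

    def test_reconstruction_error_small(self, scheme):
        """Noise-free mildly anisotropic Gaussians reconstruct to <1% RMS."""
        for evals in ([0.7e-3] * 3, [1.0e-3, 0.6e-3, 0.6e-3], [1.1e-3, 0.9e-3, 0.55e-3]):
            sig = _signal(scheme, evals)
            fit = fit_shore(sig, scheme, tau=TAU)
            e = sig / sig[scheme.b0_mask].mean()
            rec = fit.predict(scheme)
            rel_rms = np.sqrt(np.mean((rec - e) ** 2) / np.mean(e**2))
            assert rel_rms < 0.01


class TestScale:
    def test_formula_value(self, scheme):
        """zeta = 1/(8 pi^2 tau MD) for a single isotropic voxel."""
        sig = _signal(scheme, [0.7e-3] * 3)
        zeta = estimate_shore_scale(sig[None, :], scheme, tau=TAU)
        assert zeta == pytest.approx(1.0 / (8 * np.pi**2 * TAU * 0.7e-3), rel=1e-6)

    def test_inverse_proportionality(self, scheme):
        z1 = estimate_shore_scale(_signal(scheme, [0.6e-3] * 3)[None, :], scheme, TAU)
        z2 = estimate_shore_scale(_signal(scheme, [1.2e-3] * 3)[None, :], scheme, TAU)
        assert z1 / z2 == pytest.approx(2.0, rel=1e-6)

    def test_median_over_voxel_set(self, scheme):
        sigs = np.vstack([_signal(scheme, [d] * 3) for d in (0.5e-3, 0.7e-3, 0.9e-3)])
        zeta = estimate_shore_scale(sigs, scheme, TAU)
        assert zeta == pytest.approx(1.0 / (8 * np.pi**2 * TAU * 0.7e-3), rel=1e-6)


class TestIndicesGaussianOracle:
    @pytest.mark.parametrize("d", [0.5e-3, 0.7e-3, 1.0e-3, 1.5e-3])
    def test_isotropic_closed_forms(self, scheme, d):
        """Matched-scale isotropic Gaussian indices are essentially exact."""
        fit = fit_shore(_signal(scheme, [d] * 3), scheme, tau=TAU)
        rtop, rtap, rtpp, msd, gfa, pa = shore_indices(fit, np.array([0.0, 0.0, 1.0]))
        oracle = gaussian_oracle([d] * 3)
        assert rtop == pytest.approx(oracle["rtop"], rel=1e-6)
        assert rtap == pytest.approx(oracle["rtap"], rel=1e-6)
        assert rtpp == pytest.approx(oracle["rtpp"], rel=1e-6)
        assert msd == pytest.approx(oracle["msd"], rel=1e-6)
        assert gfa < 1e-3 and pa < 1e-3

    def test_moderate_anisotropy_within_5_percent(self, scheme):
        """Tensors with anisotropy ratio <= 2 (the gray-matter regime)."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            l1 = rng.uniform(0.6e-3, 1.6e-3)
            ratio = rng.uniform(1.0, 2.0)
            l2 = l1 / rng.uniform(1.0, ratio)
            l3 = l1 / ratio
            sig = _signal(scheme, [l1, l2, l3])
            fit = fit_shore(sig, scheme, tau=TAU)
            rtop, rtap, rtpp, msd, gfa, pa = shore_indices(fit, np.array([1.0, 0.0, 0.0]))
            oracle = gaussian_oracle([l1, l2, l3])
            assert rtop == pytest.approx(oracle["rtop"], rel=0.05)
            assert rtap == pytest.approx(oracle["rtap"], rel=0.05)
            assert rtpp == pytest.approx(oracle["rtpp"], rel=0.05)
            assert msd == pytest.approx(oracle["msd"], rel=0.05)
            assert 0.0 <= gfa <= 1.0 and 0.0 <= pa <= 1.0

    def test_prolate_factorization(self, scheme):
        """Separable Gaussian: RTAP(e1) * RTPP(e1) ~ RTOP (2% at mild shape)."""
        sig = _signal(scheme, [1.0e-3, 0.6e-3, 0.6e-3])
        fit = fit_shore(sig, scheme, tau=TAU)
        rtop, rtap, rtpp, *_ = shore_indices(fit, np.array([1.0, 0.0, 0.0]))
        assert rtap * rtpp == pytest.approx(rtop, rel=0.02)

    def test_monotonicity_in_diffusivity(self, scheme):
        """Larger isotropic D: lower return probabilities, larger MSD."""
        prev = None
        for d in (0.5e-3, 0.8e-3, 1.1e-3, 1.4e-3):
            fit = fit_shore(_signal(scheme, [d] * 3), scheme, tau=TAU)
            cur = shore_indices(fit, np.array([0.0, 0.0, 1.0]))
            if prev is not None:
                assert cur[0] < prev[0] and cur[1] < prev[1] and cur[2] < prev[2]
                assert cur[3] > prev[3]
            prev = cur

    def test_anisotropy_positive_for_prolate(self, scheme):
        fit = fit_shore(_signal(scheme, [1.7e-3, 0.3e-3, 0.3e-3]), scheme, tau=TAU)
        *_, gfa, pa = shore_indices(fit, np.array([1.0, 0.0, 0.0]))
        assert 0.1 < gfa <= 1.0
        assert 0.1 < pa <= 1.0

    def test_nonfinite_coefficients_give_nan(self, scheme):
        fit = fit_shore(_signal(scheme, [1e-3] * 3), scheme, tau=TAU)
        import dataclasses

        bad = dataclasses.replace(fit, coeffs=np.full(50, np.nan))
        out = shore_indices(bad, np.array([0.0, 0.0, 1.0]))
        assert all(np.isnan(v) for v in out)

    def test_axis_must_be_unit(self, scheme):
        fit = fit_shore(_signal(scheme, [1e-3] * 3), scheme, tau=TAU)
        with pytest.raises(ValueError, match="unit"):
            shore_indices(fit, np.array([1.0, 1.0, 0.0]))


class TestIndexFormulasBruteForce:
    """Index weight vectors versus direct numerical q-space integration."""

    def test_random_coefficients_match_quadrature(self):
        from scipy.special import genlaguerre

        from gmshore.shore import _kappa_const, real_sph_harm

        order, zeta = 6, 700.0
        idx = shore_index_list(order)
        eng = ShoreIndexEngine(order, zeta, TAU)
        rng = np.random.default_rng(3)

        def e_of_q(qvecs, c):
            q = np.linalg.norm(qvecs, axis=-1)
            u = np.where(q[:, None] > 0, qvecs / np.maximum(q, 1e-300)[:, None],
                         [0.0, 0.0, 1.0])
            y = real_sph_harm(idx, u)
            s2 = q**2 / zeta
            out = np.zeros(len(qvecs))
            for j, (n, l, m) in enumerate(idx):
                rad = (zeta**-0.75 * _kappa_const(n, l) * s2 ** (l / 2)
                       * np.exp(-s2 / 2) * genlaguerre(n - l, l + 0.5)(s2))
                out += c[j] * rad * y[:, j]
            return out

        nodes, weights = np.polynomial.legendre.leggauss(120)
        r = 0.5 * 10 * np.sqrt(zeta) * (nodes + 1)
        wr = 0.5 * 10 * np.sqrt(zeta) * weights
        axis = np.array([0.0, 0.0, 1.0])
        c = rng.standard_normal(len(idx)) * np.exp(-0.5 * np.arange(len(idx)) / 10)

        # RTPP: line integral along the axis
        line = np.outer(r, axis)
        rtpp_bf = float((wr * (e_of_q(line, c) + e_of_q(-line, c))).sum())
        # RTAP: polar integral over the orthogonal plane
        phis = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        plane = np.stack([np.outer(r, np.cos(phis)).ravel(),
                          np.outer(r, np.sin(phis)).ravel(),
                          np.zeros(r.size * phis.size)], axis=1)
        ep = e_of_q(plane, c).reshape(r.size, phis.size)
        rtap_bf = float(((wr * r)[:, None] * ep).sum() * (2 * np.pi / phis.size))
        # RTOP: full q-space integral
        ct, wct = np.polynomial.legendre.leggauss(60)
        st = np.sqrt(1 - ct**2)
        qgrid = np.stack([
            np.einsum("i,j,k->ijk", r, st, np.cos(phis)).ravel(),
            np.einsum("i,j,k->ijk", r, st, np.sin(phis)).ravel(),
            np.einsum("i,j,k->ijk", r, ct, np.ones_like(phis)).ravel(),
        ], axis=1)
        ev = e_of_q(qgrid, c).reshape(r.size, ct.size, phis.size)
        w3 = (wr * r**2)[:, None, None] * wct[None, :, None] * (2 * np.pi / phis.size)
        rtop_bf = float((ev * w3).sum())

        res = eng.all_indices(c[None, :], axis[None, :])
        assert res["rtop"][0] == pytest.approx(rtop_bf, rel=1e-10)
        assert res["rtpp"][0] == pytest.approx(rtpp_bf, rel=1e-10)
        assert res["rtap"][0] == pytest.approx(rtap_bf, rel=1e-10)


class TestComputeIndexMaps:
    def test_homogeneous_block(self, scheme):
        sig = _signal(scheme, [0.9e-3, 0.7e-3, 0.6e-3])
        block = np.tile(sig, (6, 1))
        maps = compute_index_maps(block, scheme)
        for name in ("fa", "md", "rtop", "gfa", "pa", "msd", "rtap", "rtpp"):
            vals = maps[name]
            assert np.all(np.isfinite(vals))
            assert np.allclose(vals, vals[0], rtol=1e-6)

    def test_corrupted_voxel_isolated(self, scheme):
        sig = _signal(scheme, [1e-3] * 3)
        block = np.vstack([sig, np.zeros(len(scheme)), sig])
        maps = compute_index_maps(block, scheme)
        assert np.all(np.isnan(maps["rtop"][[1]]))
        assert np.all(np.isfinite(maps["rtop"][[0, 2]]))

    def test_prolate_block_fa(self, scheme):
        ev = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        block = np.tile(_signal(scheme, ev), (4, 1))
        maps = compute_index_maps(block, scheme)
        md = ev.mean()
        fa_expected = np.sqrt(1.5 * np.sum((ev - md) ** 2) / np.sum(ev**2))
        assert np.allclose(maps["fa"], fa_expected, atol=1e-6)

    def test_length_mismatch(self, scheme):
        with pytest.raises(ValueError, match="measurements"):
            compute_index_maps(np.ones((3, 10)), scheme)

    def test_anisotropies_in_unit_interval(self, scheme):
        rng = np.random.default_rng(1)
        block = np.vstack([
            _signal(scheme, sorted(rng.uniform(0.3e-3, 1.5e-3, 3), reverse=True))
            for _ in range(8)
        ])
        maps = compute_index_maps(block, scheme)
        for name in ("fa", "gfa", "pa"):
            assert np.all((maps[name] >= 0) & (maps[name] <= 1))
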